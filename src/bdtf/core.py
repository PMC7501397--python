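"""Asymmetric difficulty-update recursion on the unit interval.

The controller presents a task of difficulty ``d(t) ∈ [0, 1]`` and observes a
binary outcome ``x(t)``.  The next difficulty is

    d(t+1) = min(1, d(t) + λ(1 − s*))   if x(t) = 1 (success)
    d(t+1) = max(0, d(t) − λ s*)        if x(t) = 0 (failure)

where ``λ`` is the step size and ``s*`` the target success probability.  The
asymmetry (up-step λ(1−s*), down-step λs*) is what makes the recursion settle
where the learner succeeds with probability s* rather than 50%: the expected
move is zero exactly when ``P(success) = s*``.

An equivalent form projects the unconstrained update onto ``H = [0, 1]``:
``d(t+1) = Π_H(d(t) + λ(x(t) − s*))``.  The clipped form is canonical here;
:func:`step_equivalence_check` verifies the two agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "ControllerConfig",
    "DifficultyState",
    "step",
    "project_unit",
    "increments",
    "step_equivalence_check",
]


@dataclass(frozen=True)
class ControllerConfig:
    """Fixed parameters of the update rule.

    Parameters
    ----------
    lam:
        Update (step-size) parameter λ, strictly inside (0, 1).  Small values
        give slow, smooth, accurate convergence; large values fast, noisy
        convergence.
    target:
        Target success probability s*, strictly inside (0, 1).
    d0:
        Initial difficulty d(0) in [0, 1].  Defaults to 0.5 — start at a
        medium-level task.
    """

    lam: float
    target: float
    d0: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.lam < 1.0):
            raise ValueError(f"lam must lie strictly in (0, 1), got {self.lam}")
        if not (0.0 < self.target < 1.0):
            raise ValueError(
                f"target must lie strictly in (0, 1), got {self.target}"
            )
        if not (0.0 <= self.d0 <= 1.0):
            raise ValueError(f"d0 must lie in [0, 1], got {self.d0}")

    def with_target(self, target: float) -> "ControllerConfig":
        """Copy of this config with a different target (for mid-session changes)."""
        return replace(self, target=target)


@dataclass(frozen=True)
class DifficultyState:
    """Trial counter and current difficulty.

    ``d`` is the difficulty of the task presented at trial ``t`` (0-based),
    before its outcome is observed.
    """

    t: int
    d: float

    def __post_init__(self) -> None:
        if self.t < 0:
            raise ValueError(f"trial index must be >= 0, got {self.t}")
        if not (0.0 <= self.d <= 1.0):
            raise ValueError(f"difficulty must lie in [0, 1], got {self.d}")


def increments(config: ControllerConfig) -> tuple[float, float]:
    """Up- and down-step sizes ``(λ(1−s*), λs*)``.

    Their sum is λ and their ratio ``(1−s*)/s*`` — the asymmetry that encodes
    the target: for s* = 0.7 each failure moves difficulty 7/3 times as far
    down as each success moves it up.
    """
    return config.lam * (1.0 - config.target), config.lam * config.target


def step(
    state: DifficultyState, outcome: int, config: ControllerConfig
) -> DifficultyState:
    """Apply one update of the recursion.

    Parameters
    ----------
    state:
        Current :class:`DifficultyState`.
    outcome:
        Binary result of the presented task: 1 success, 0 failure.
    config:
        Controller parameters.

    Returns
    -------
    DifficultyState
        Trial index incremented, difficulty updated and clipped to [0, 1].
    """
    if outcome not in (0, 1):
        raise ValueError(f"outcome must be 0 or 1, got {outcome!r}")
    up, down = increments(config)
    if outcome == 1:
        d_new = min(1.0, state.d + up)
    else:
        d_new = max(0.0, state.d - down)
    return DifficultyState(t=state.t + 1, d=d_new)


def project_unit(d_raw: float) -> float:
    """Projection Π_H onto H = [0, 1]: identity inside, clamp outside."""
    if not math.isfinite(d_raw):
        raise ValueError(f"difficulty must be finite, got {d_raw}")
    if d_raw >= 1.0:
        return 1.0
    if d_raw <= 0.0:
        return 0.0
    return d_raw


def step_equivalence_check(
    state: DifficultyState, outcome: int, config: ControllerConfig
) -> bool:
    """True iff the clipped update equals ``Π_H(d + λ(x − s*))`` exactly.

    The two forms are algebraically identical (x − s* equals 1 − s* or −s*),
    so this should hold to full floating precision for every input; it exists
    as an independent oracle for property tests.
    """
    clipped = step(state, outcome, config).d
    projected = project_unit(state.d + config.lam * (outcome - config.target))
    return clipped == projected
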