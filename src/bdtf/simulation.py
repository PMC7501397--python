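"""Trial-by-trial session engine and replication harness.

A session presents tasks to a simulated learner: at trial t the task has
difficulty d(t), the outcome is a Bernoulli draw with success probability
S(d(t)), and the difficulty is updated by the asymmetric rule.  The target
success probability may change mid-session via a piecewise-constant
:class:`TargetSchedule` (teacher intervention), and :func:`replicate` runs
independent seeded sessions for Monte-Carlo summaries.

Two notions of "time to converge" are provided:

* :func:`convergence_time` — first trial from which the difficulty stays
  within an ε-band of the limit for the remainder of the run (a last-exit
  statistic; its value grows with the horizon whenever the steady-state
  oscillation can leave the band);
* :func:`first_hitting_time` — first trial at which the trajectory reaches
  or crosses the limit value.  This is the measure that is monotone in λ
  (bigger steps reach the limit sooner).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .core import ControllerConfig, increments
from .learners import SkillCurve

__all__ = [
    "TargetSchedule",
    "Trajectory",
    "ReplicateSummary",
    "run_session",
    "convergence_time",
    "first_hitting_time",
    "replicate",
    "tracking_experiment",
    "terminal_window_size",
    "spawn_seeds",
]

#: default ε-band half-width for convergence detection
DEFAULT_EPSILON = 0.05
#: minimum number of in-band trials that must follow a convergence point
DEFAULT_WINDOW = 10
#: stride between per-replicate seeds derived from a base seed
SEED_STRIDE = 10007


@dataclass(frozen=True)
class TargetSchedule:
    """Piecewise-constant target success probability s*(t).

    ``breakpoints`` are increasing trial indices starting at 0; segment i
    uses ``targets[i]`` from ``breakpoints[i]`` up to the next breakpoint.
    """

    breakpoints: tuple[int, ...]
    targets: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.breakpoints) != len(self.targets) or not self.breakpoints:
            raise ValueError("breakpoints and targets must be equal-length, non-empty")
        if self.breakpoints[0] != 0:
            raise ValueError("first breakpoint must be 0")
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if any(not (0.0 < s < 1.0) for s in self.targets):
            raise ValueError("every target must lie strictly in (0, 1)")

    @classmethod
    def constant(cls, target: float) -> "TargetSchedule":
        return cls(breakpoints=(0,), targets=(target,))

    def target_at(self, t: int) -> float:
        """Active target for trial t."""
        idx = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return self.targets[idx]

    def per_trial(self, n_steps: int) -> np.ndarray:
        """Active target for each of trials 0..n_steps-1."""
        out = np.empty(n_steps)
        for i, (start, s) in enumerate(zip(self.breakpoints, self.targets)):
            end = self.breakpoints[i + 1] if i + 1 < len(self.breakpoints) else n_steps
            out[start:end] = s
        return out


@dataclass(frozen=True)
class Trajectory:
    """One session: per-trial difficulty, outcome and active target.

    ``d[t]`` is the difficulty of the task *presented* at trial t (before its
    outcome is observed); ``d_end`` is the difficulty the controller would
    present next after the final trial.
    """

    t: np.ndarray
    d: np.ndarray
    x: np.ndarray
    s_target: np.ndarray
    seed: int
    d_end: float

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.d) == len(self.x) == len(self.s_target) == n):
            raise ValueError("trajectory columns must have equal length")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def difficulties_with_end(self) -> np.ndarray:
        """All n+1 difficulties including the post-session one."""
        return np.append(self.d, self.d_end)


@dataclass(frozen=True)
class ReplicateSummary:
    """Monte-Carlo summary over independent sessions."""

    n_replicates: int
    seeds: tuple[int, ...]
    mean_path: np.ndarray
    std_path: np.ndarray
    terminal_means: np.ndarray          # per-replicate terminal-window mean of d
    terminal_success_rates: np.ndarray  # per-replicate terminal-window mean of x
    convergence_times: tuple[Optional[int], ...]
    first_hit_times: tuple[Optional[int], ...]
    trajectories: tuple[Trajectory, ...] = ()

    @property
    def terminal_mean(self) -> float:
        return float(self.terminal_means.mean())

    def median_convergence_time(self, censor_at: Optional[int] = None) -> float:
        """Median convergence time; non-converged replicates are treated as
        censored at ``censor_at`` (required if any replicate did not converge)."""
        times = []
        for ct in self.convergence_times:
            if ct is None:
                if censor_at is None:
                    raise ValueError(
                        "non-converged replicates present; pass censor_at"
                    )
                times.append(censor_at)
            else:
                times.append(ct)
        return float(np.median(times))


def terminal_window_size(n_steps: int) -> int:
    """Window for steady-state statistics: last 10% of trials, at least 100."""
    return min(n_steps, max(100, n_steps // 10))


def run_session(
    curve: SkillCurve,
    config: ControllerConfig,
    schedule: Optional[TargetSchedule] = None,
    n_steps: int = 2000,
    seed: int = 0,
) -> Trajectory:
    """Simulate one session of ``n_steps`` trials.

    At each trial the presented difficulty is recorded, the outcome drawn
    from the learner's skill curve, and the difficulty updated with the
    schedule's active target (``config.target`` if no schedule is given).
    Fully reproducible from ``seed``.
    """
    if n_steps < 1:
        raise ValueError(f"n_steps must be >= 1, got {n_steps}")
    if schedule is None:
        schedule = TargetSchedule.constant(config.target)
    rng = np.random.default_rng(seed)
    s_per_trial = schedule.per_trial(n_steps)
    uniforms = rng.random(n_steps)

    d_arr = np.empty(n_steps)
    x_arr = np.empty(n_steps, dtype=np.int64)
    d = config.d0
    lam = config.lam
    for t in range(n_steps):
        d_arr[t] = d
        x = 1 if uniforms[t] < curve(d) else 0
        x_arr[t] = x
        s = s_per_trial[t]
        if x:
            d = min(1.0, d + lam * (1.0 - s))
        else:
            d = max(0.0, d - lam * s)
    return Trajectory(
        t=np.arange(n_steps),
        d=d_arr,
        x=x_arr,
        s_target=s_per_trial,
        seed=seed,
        d_end=d,
    )


def convergence_time(
    traj: Trajectory,
    d_target: float,
    epsilon: float = DEFAULT_EPSILON,
    window: int = DEFAULT_WINDOW,
) -> Optional[int]:
    """First trial from which |d − d_target| ≤ ε holds to the end of the run.

    The convergence point must be followed by at least ``window`` further
    trials (a hit in the last few trials does not count).  Returns ``None``
    if the trajectory never settles.  Being a last-exit statistic, the value
    depends on the run length whenever in-band residence is not permanent.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be > 0, got {epsilon}")
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    d = traj.d
    ok = np.abs(d - d_target) <= epsilon
    bad = np.nonzero(~ok)[0]
    t_conv = 0 if bad.size == 0 else int(bad[-1]) + 1
    if len(d) - 1 - t_conv < window:
        return None
    return t_conv


def first_hitting_time(traj: Trajectory, d_target: float) -> Optional[int]:
    """First trial at which the difficulty reaches or crosses ``d_target``."""
    d = traj.d
    signs = np.sign(d - d_target)
    hits = np.nonzero((signs == 0) | (signs != signs[0]))[0]
    return int(hits[0]) if hits.size else None


def spawn_seeds(base_seed: int, n: int) -> tuple[int, ...]:
    """Deterministic per-replicate seeds: fixed stride from the base seed."""
    return tuple(int((base_seed + i * SEED_STRIDE) % 2**31) for i in range(n))


def replicate(
    curve: SkillCurve,
    config: ControllerConfig,
    schedule: Optional[TargetSchedule] = None,
    n_steps: int = 2000,
    n_replicates: int = 50,
    base_seed: int = 0,
    d_star: Optional[float] = None,
    epsilon: float = DEFAULT_EPSILON,
    window: int = DEFAULT_WINDOW,
    keep_trajectories: bool = False,
) -> ReplicateSummary:
    """Run independent seeded sessions and summarise them.

    ``d_star`` (the theoretical limit) enables per-replicate convergence and
    first-hitting times; terminal statistics use the last-10% window.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    seeds = spawn_seeds(base_seed, n_replicates)
    w = terminal_window_size(n_steps)
    paths = np.empty((n_replicates, n_steps))
    term_d = np.empty(n_replicates)
    term_x = np.empty(n_replicates)
    conv_times: list[Optional[int]] = []
    hit_times: list[Optional[int]] = []
    kept = []
    for i, seed in enumerate(seeds):
        traj = run_session(curve, config, schedule, n_steps, seed)
        paths[i] = traj.d
        term_d[i] = traj.d[-w:].mean()
        term_x[i] = traj.x[-w:].mean()
        if d_star is not None:
            conv_times.append(convergence_time(traj, d_star, epsilon, window))
            hit_times.append(first_hitting_time(traj, d_star))
        if keep_trajectories:
            kept.append(traj)
    return ReplicateSummary(
        n_replicates=n_replicates,
        seeds=seeds,
        mean_path=paths.mean(axis=0),
        std_path=paths.std(axis=0),
        terminal_means=term_d,
        terminal_success_rates=term_x,
        convergence_times=tuple(conv_times),
        first_hit_times=tuple(hit_times),
        trajectories=tuple(kept),
    )


def tracking_experiment(
    curve: SkillCurve,
    lam: float = 0.01,
    n_steps: int = 4000,
    switch_t: int = 1500,
    s_before: float = 0.7,
    s_after: float = 0.9,
    seed: int = 0,
    d0: float = 0.5,
) -> Trajectory:
    """Mid-session target change: run with s* = s_before until ``switch_t``,
    then s* = s_after — the teacher deciding the learner should succeed more
    often, which moves the operating difficulty from S⁻¹(s_before) down to
    S⁻¹(s_after)."""
    if not (0 < switch_t < n_steps):
        raise ValueError(f"switch_t must lie in (0, n_steps), got {switch_t}")
    if s_before == s_after:
        schedule = TargetSchedule.constant(s_before)
    else:
        schedule = TargetSchedule(breakpoints=(0, switch_t), targets=(s_before, s_after))
    config = ControllerConfig(lam=lam, target=s_before, d0=d0)
    return run_session(curve, config, schedule, n_steps, seed)
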