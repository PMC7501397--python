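"""Mean-field and stationary analysis of the difficulty recursion.

As the step size λ → 0 the stochastic recursion tracks, in the rescaled time
τ = λt, the mean-field ODE

    ḋ = S(d) − s*,

whose unique attractor on [0, 1] is the interior fixed point d* = S⁻¹(s*)
when s* lies in the range of S, and otherwise the boundary 0 (when
max S < s*) or 1 (when min S > s*).  This module provides

* :func:`expected_drift` — the exact one-step expected movement
  λ(S(d) − s*), valid away from the clipping bands;
* :func:`ode_limit` — a fixed-step RK4 integration of the ODE;
* :func:`stationary_oracle` — an independent numerical check: the recursion
  restricted to a fine difficulty grid is a finite Markov chain whose
  stationary distribution is found by power iteration; its mean must approach
  the theoretical limit as λ shrinks;
* :func:`predict_limit` — the case label and limiting difficulty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from .core import ControllerConfig, increments
from .learners import (
    INTERIOR,
    LOWER_BOUNDARY,
    SkillCurve,
    UPPER_BOUNDARY,
    classify_case,
    invert,
)

__all__ = [
    "ODEPath",
    "StationaryDistribution",
    "ConvergenceReport",
    "expected_drift",
    "ode_limit",
    "stationary_oracle",
    "predict_limit",
]

#: default RK4 step in rescaled time τ = λt
ODE_STEP = 0.01


@dataclass(frozen=True)
class ODEPath:
    """Solution of ḋ = S(d) − s* on a uniform grid of rescaled time."""

    times: np.ndarray
    values: np.ndarray

    @property
    def terminal(self) -> float:
        return float(self.values[-1])


@dataclass(frozen=True)
class StationaryDistribution:
    """Probability mass over a uniform difficulty grid."""

    grid: np.ndarray
    mass: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.dot(self.grid, self.mass))

    def mass_below(self, d: float) -> float:
        """Total stationary mass at difficulties <= d."""
        return float(self.mass[self.grid <= d].sum())


@dataclass(frozen=True)
class ConvergenceReport:
    """Limit prediction plus convergence-time statistics over replicates."""

    case_label: str
    d_star: float
    convergence_times: tuple[Optional[int], ...] = ()
    summary: dict = field(default_factory=dict)


def expected_drift(curve: SkillCurve, config: ControllerConfig, d: float) -> float:
    """Exact expected one-step movement E[d(t+1) − d(t) | d(t) = d].

    Enumerating both outcomes, success (probability S(d)) moves up λ(1 − s*)
    and failure moves down λs*, giving λ(S(d) − s*).  The identity requires
    neither clip to be active, i.e. d ∈ [λs*, 1 − λ(1 − s*)]; outside that
    band a ``ValueError`` signals that the clipped drift differs.
    """
    up, down = increments(config)
    if d < down or d > 1.0 - up:
        raise ValueError(
            f"d={d} lies in a clipping band; the unclipped drift identity "
            f"holds only on [{down}, {1.0 - up}]"
        )
    s = curve(d)
    return s * up - (1.0 - s) * down


def ode_limit(
    curve: SkillCurve,
    s_target: float,
    d0: float = 0.5,
    horizon: float = 20.0,
    step: float = ODE_STEP,
) -> ODEPath:
    """Integrate ḋ = S(d) − s* from d0 over [0, horizon] in rescaled time.

    Classical fixed-step 4th-order Runge–Kutta with the state clipped to
    [0, 1] after every step; S is smooth and bounded so a fixed step
    suffices (validated in tests against a 10×-finer reference).
    """
    if not (0.0 <= d0 <= 1.0):
        raise ValueError(f"d0 must lie in [0, 1], got {d0}")
    if horizon <= 0 or step <= 0:
        raise ValueError("horizon and step must be > 0")

    def rhs(d: float) -> float:
        return curve(min(1.0, max(0.0, d))) - s_target

    n = int(round(horizon / step))
    times = np.linspace(0.0, n * step, n + 1)
    values = np.empty(n + 1)
    values[0] = d0
    d = d0
    for i in range(n):
        k1 = rhs(d)
        k2 = rhs(d + 0.5 * step * k1)
        k3 = rhs(d + 0.5 * step * k2)
        k4 = rhs(d + step * k3)
        d = d + step * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
        d = min(1.0, max(0.0, d))
        values[i + 1] = d
    return ODEPath(times=times, values=values)


def _transition_matrix(
    curve: SkillCurve, config: ControllerConfig, grid: np.ndarray
) -> sp.csr_matrix:
    """Row-stochastic transition matrix of the grid-restricted recursion.

    From grid point d: up λ(1−s*) with probability S(d), down λs* otherwise;
    destinations rounded to the nearest grid point and clipped at the sticky
    boundaries (matching the min/max form of the update).
    """
    n = grid.size
    spacing = grid[1] - grid[0]
    up, down = increments(config)
    s_vals = np.array([curve(float(d)) for d in grid])
    up_idx = np.clip(np.rint((grid + up) / spacing).astype(int), 0, n - 1)
    down_idx = np.clip(np.rint((grid - down) / spacing).astype(int), 0, n - 1)
    rows = np.concatenate([np.arange(n), np.arange(n)])
    cols = np.concatenate([up_idx, down_idx])
    probs = np.concatenate([s_vals, 1.0 - s_vals])
    return sp.csr_matrix((probs, (rows, cols)), shape=(n, n))


def _lattice_grid_n(config: ControllerConfig, max_points: int) -> Optional[int]:
    """Grid size on which both step sizes are exact integer multiples.

    For a rational target s* = p/q (reduced), the recursion started on the
    lattice {k·λ/q} stays on it: the up-step is (q−p) lattice units and the
    down-step p units, which are coprime, so the grid chain is irreducible
    and reproduces the continuum process exactly.  Returns ``None`` when the
    target has no small-denominator representation or the lattice is too big.
    """
    from fractions import Fraction

    frac = Fraction(config.target).limit_denominator(1000)
    if abs(float(frac) - config.target) > 1e-9:
        return None
    n_cells = frac.denominator / config.lam
    if abs(n_cells - round(n_cells)) > 1e-6 or round(n_cells) > max_points - 1:
        return None
    return int(round(n_cells)) + 1


def stationary_oracle(
    curve: SkillCurve,
    config: ControllerConfig,
    grid_n: Optional[int] = None,
    tol: float = 1e-12,
    max_iter: int = 1_000_000,
) -> StationaryDistribution:
    """Stationary distribution of the recursion restricted to a difficulty grid.

    With ``grid_n=None`` the grid is the exact step lattice whenever the
    target is rational with a small denominator (both steps are then integer
    multiples of the spacing and the chain is the continuum process itself,
    restricted to its reachable lattice); otherwise a fine rounding grid is
    used whose spacing resolves both steps (< half the smaller one).  An
    explicitly supplied ``grid_n`` uses nearest-grid rounding and is rejected
    when too coarse.

    The stationary mass is found by power iteration on the half-lazy kernel
    (I + P)/2 — same stationary distribution as P, but aperiodic, so the
    iteration converges even though the step pattern makes the raw chain
    periodic — until successive distributions differ by less than ``tol`` in
    total variation.

    This is a deliberately independent route to the long-run behaviour: no
    trajectory simulation, no ODE — just the transition kernel of the chain.
    """
    up, down = increments(config)
    min_step = min(up, down)
    needed = int(np.ceil(2.0 / min_step)) + 2
    if grid_n is None:
        grid_n = _lattice_grid_n(config, max_points=200_001)
        if grid_n is None:
            grid_n = max(4001, needed)
    elif (grid_n - 1) < 2.0 / min_step:
        raise ValueError(
            f"grid_n={grid_n} too coarse for step sizes ({up}, {down}); "
            f"need at least {needed} points"
        )
    grid = np.linspace(0.0, 1.0, grid_n)
    P = _transition_matrix(curve, config, grid)
    pi = np.full(grid_n, 1.0 / grid_n)
    for _ in range(max_iter):
        pi_next = 0.5 * (pi + pi @ P)
        if 0.5 * np.abs(pi_next - pi).sum() < tol:
            pi = pi_next
            break
        pi = pi_next
    pi = np.asarray(pi).ravel()
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    return StationaryDistribution(grid=grid, mass=pi)


def predict_limit(curve: SkillCurve, s_target: float) -> tuple[str, float]:
    """Case label and limiting difficulty for a curve/target pair.

    interior → (interior, S⁻¹(s*)); target above the whole curve →
    (lower_boundary, 0); target below the whole curve → (upper_boundary, 1).
    """
    label = classify_case(curve, s_target)
    if label == LOWER_BOUNDARY:
        return label, 0.0
    if label == UPPER_BOUNDARY:
        return label, 1.0
    return INTERIOR, invert(curve, s_target)
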