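"""Simulated learners: monotone skill curves and Bernoulli responses.

A learner is summarised by a skill curve ``S(d)`` — the probability of
succeeding at a task of difficulty ``d`` — assumed monotone non-increasing on
[0, 1] with values in [0, 1].  Three families are provided:

* :class:`LogisticSkillCurve` — ``S(d) = a − b / (1 + exp(−k(d − center)))``
  with ``0 < b ≤ a ≤ 1``, the smooth family used in the simulation studies
  (defaults k = 20, center = 0.5);
* :class:`StepSkillCurve` — a two-level stair: high performance up to a
  threshold, low performance above it (the stochastic-point-location setting);
* :class:`TabulatedSkillCurve` — piecewise-linear interpolation of monotone
  knots, for arbitrary empirical curves.

The inverse ``d* = S⁻¹(s*)`` is the controller's interior fixed point; it is
found by monotone bisection so that discontinuous (step) and flat (tabulated)
curves are handled with defined tie-breaking.
"""

from __future__ import annotations

import math
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SkillCurve",
    "LogisticSkillCurve",
    "StepSkillCurve",
    "TabulatedSkillCurve",
    "curve_from_spec",
    "success_probability",
    "sample_response",
    "invert",
    "classify_case",
    "validate_monotone",
    "INTERIOR",
    "LOWER_BOUNDARY",
    "UPPER_BOUNDARY",
]

# Theorem-case labels: where the recursion settles as λ → 0.
INTERIOR = "interior"          # min S ≤ s* ≤ max S  →  d* = S⁻¹(s*)
LOWER_BOUNDARY = "lower_boundary"  # max S < s*  →  d* = 0
UPPER_BOUNDARY = "upper_boundary"  # min S > s*  →  d* = 1

#: bisection stops when the bracket is narrower than this
BISECTION_TOL = 1e-10
BISECTION_MAX_ITER = 200


class SkillCurve(ABC):
    """Success probability as a monotone non-increasing function of difficulty."""

    @abstractmethod
    def __call__(self, d: float) -> float:
        """Evaluate S(d) for d in [0, 1]."""

    @property
    def max_success(self) -> float:
        """max S over [0, 1] (= S(0) by monotonicity)."""
        return self(0.0)

    @property
    def min_success(self) -> float:
        """min S over [0, 1] (= S(1) by monotonicity)."""
        return self(1.0)


def _check_difficulty(d: float) -> float:
    if not (0.0 <= d <= 1.0):
        raise ValueError(f"difficulty must lie in [0, 1], got {d}")
    return float(d)


@dataclass(frozen=True)
class LogisticSkillCurve(SkillCurve):
    """``S(d) = a − b / (1 + exp(−k(d − center)))``.

    ``a`` is the ceiling of the success probability (approached for easy
    tasks), ``a − b`` its floor for hard tasks, ``k`` the steepness and
    ``center`` the inflection difficulty.  ``0 < b ≤ a ≤ 1`` guarantees the
    curve is decreasing with values in [0, 1].
    """

    a: float = 1.0
    b: float = 1.0
    k: float = 20.0
    center: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.b <= self.a <= 1.0):
            raise ValueError(
                f"logistic curve requires 0 < b <= a <= 1, got a={self.a}, b={self.b}"
            )
        if self.k <= 0:
            raise ValueError(f"steepness k must be > 0, got {self.k}")

    def __call__(self, d: float) -> float:
        d = _check_difficulty(d)
        return self.a - self.b / (1.0 + math.exp(-self.k * (d - self.center)))

    def inverse_closed_form(self, s: float) -> float:
        """Analytic inverse d = center − ln((b − a + s)/(a − s)) / k.

        Defined for s strictly between the curve's values at the ends of the
        real line (a − b, a); the result may fall outside [0, 1] when s is
        beyond the range attained on the unit interval.
        """
        if not (self.a - self.b < s < self.a):
            raise ValueError(f"s={s} outside the open range of the logistic curve")
        return self.center - math.log((self.b - self.a + s) / (self.a - s)) / self.k


@dataclass(frozen=True)
class StepSkillCurve(SkillCurve):
    """Two-level stair: success probability p_high for d ≤ theta, p_low above."""

    theta: float = 0.5
    p_high: float = 0.9
    p_low: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta <= 1.0):
            raise ValueError(f"theta must lie in [0, 1], got {self.theta}")
        if not (1.0 >= self.p_high > self.p_low >= 0.0):
            raise ValueError(
                f"need 1 >= p_high > p_low >= 0, got {self.p_high}, {self.p_low}"
            )

    def __call__(self, d: float) -> float:
        d = _check_difficulty(d)
        return self.p_high if d <= self.theta else self.p_low


@dataclass(frozen=True)
class TabulatedSkillCurve(SkillCurve):
    """Piecewise-linear interpolation of monotone (d, S) knots.

    Knot difficulties must be strictly increasing and cover [0, 1] endpoints
    implicitly: evaluation outside the knot span holds the end values.
    """

    knots: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: ((0.0, 1.0), (1.0, 0.0))
    )

    def __post_init__(self) -> None:
        ds = [kd for kd, _ in self.knots]
        ss = [ks for _, ks in self.knots]
        if len(self.knots) < 2:
            raise ValueError("need at least two knots")
        if any(d2 <= d1 for d1, d2 in zip(ds, ds[1:])):
            raise ValueError("knot difficulties must be strictly increasing")
        if any(s2 > s1 for s1, s2 in zip(ss, ss[1:])):
            raise ValueError("knot values must be non-increasing")
        if any(not (0.0 <= s <= 1.0) for s in ss) or any(
            not (0.0 <= d <= 1.0) for d in ds
        ):
            raise ValueError("knots must lie in the unit square")

    def __call__(self, d: float) -> float:
        d = _check_difficulty(d)
        ds = [kd for kd, _ in self.knots]
        ss = [ks for _, ks in self.knots]
        return float(np.interp(d, ds, ss))


_FAMILIES = {
    "logistic": LogisticSkillCurve,
    "step": StepSkillCurve,
    "tabulated": TabulatedSkillCurve,
}


def curve_from_spec(family: str, **params) -> SkillCurve:
    """Build a skill curve from a family name and keyword parameters.

    This is the serialisable form used in run-config files, e.g.
    ``family: logistic, a: 1.0, b: 1.0``.  Tabulated knots may be given as a
    list of [d, S] pairs.
    """
    try:
        cls = _FAMILIES[family]
    except KeyError:
        raise ValueError(
            f"unknown skill-curve family {family!r}; known: {sorted(_FAMILIES)}"
        ) from None
    if cls is TabulatedSkillCurve and "knots" in params:
        params = dict(params, knots=tuple(tuple(k) for k in params["knots"]))
    return cls(**params)


def success_probability(curve: SkillCurve, d: float) -> float:
    """Evaluate S(d); raises if d is outside [0, 1]."""
    return curve(d)


def sample_response(curve: SkillCurve, d: float, rng: np.random.Generator) -> int:
    """Draw a binary outcome: 1 with probability S(d), else 0."""
    return int(rng.random() < curve(d))


def invert(curve: SkillCurve, s_target: float, tol: float = BISECTION_TOL) -> float:
    """Difficulty d* with S(d*) = s_target, by monotone bisection on [0, 1].

    Ties (flat segments at the target value) resolve to the smallest
    difficulty achieving the target — the easiest qualifying task; for a step
    curve and a target strictly between its two levels, the jump location
    theta is returned.

    Raises ``ValueError`` when s_target is outside [min S, max S]; callers
    facing that should consult :func:`classify_case` instead.
    """
    if not (curve.min_success <= s_target <= curve.max_success):
        raise ValueError(
            f"target {s_target} outside the curve's range "
            f"[{curve.min_success}, {curve.max_success}]; see classify_case"
        )
    if curve(0.0) <= s_target:
        return 0.0
    # Invariant: S(lo) > s_target >= S(hi); the bracket contracts onto the
    # left edge of {d : S(d) <= s_target}.
    lo, hi = 0.0, 1.0
    for _ in range(BISECTION_MAX_ITER):
        if hi - lo <= 2.0 * tol:
            break
        mid = 0.5 * (lo + hi)
        if curve(mid) > s_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def classify_case(curve: SkillCurve, s_target: float) -> str:
    """Which limit the recursion approaches for this curve and target.

    ``interior`` when min S ≤ s* ≤ max S (fixed point S⁻¹(s*)); otherwise the
    difficulty drifts to a boundary: ``lower_boundary`` (limit 0) when even
    the easiest task is failed too often (max S < s*), ``upper_boundary``
    (limit 1) when even the hardest task is succeeded too often (min S > s*).
    Equality at either end counts as interior.
    """
    if curve.max_success < s_target:
        return LOWER_BOUNDARY
    if curve.min_success > s_target:
        return UPPER_BOUNDARY
    return INTERIOR


def validate_monotone(curve: SkillCurve, grid_n: int = 101) -> bool:
    """Check the skill-curve contract on a uniform grid.

    True iff S is non-increasing and within [0, 1] at ``grid_n`` equally
    spaced difficulties.
    """
    if grid_n < 2:
        raise ValueError(f"grid_n must be >= 2, got {grid_n}")
    values = [curve(d) for d in np.linspace(0.0, 1.0, grid_n)]
    if any(not (0.0 <= v <= 1.0) for v in values):
        return False
    return all(v2 <= v1 + 1e-12 for v1, v2 in zip(values, values[1:]))
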