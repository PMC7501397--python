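"""Skill curves: evaluation, inversion, classification, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bdtf.learners import (
    INTERIOR,
    LOWER_BOUNDARY,
    UPPER_BOUNDARY,
    LogisticSkillCurve,
    StepSkillCurve,
    TabulatedSkillCurve,
    classify_case,
    curve_from_spec,
    invert,
    sample_response,
    success_probability,
    validate_monotone,
)

CASE1 = LogisticSkillCurve(a=1.0, b=1.0)
CASE2 = LogisticSkillCurve(a=0.6, b=0.5)
CASE3 = LogisticSkillCurve(a=1.0, b=0.2)


@pytest.mark.parametrize(
    "curve, d, expected",
    [
        (CASE1, 0.5, 0.5),                        # a − b/2 at the center
        (LogisticSkillCurve(a=0.6, b=0.5), 0.5, 0.35),
        (CASE1, 0.0, 1.0 - 1.0 / (1.0 + math.exp(10.0))),  # ≈ 0.9999546
        (CASE1, 1.0, 1.0 / (1.0 + math.exp(10.0))),
    ],
)
def test_logistic_values(curve, d, expected):
    assert success_probability(curve, d) == pytest.approx(expected, abs=1e-12)


def test_evaluation_rejects_out_of_range_difficulty():
    with pytest.raises(ValueError):
        CASE1(1.2)


@pytest.mark.parametrize(
    "target, expected, tol",
    [
        (0.7, 0.458, 1e-3),   # interior fixed point of the case-1 curve
        (0.9, 0.390, 1e-3),   # after the target change
        (0.5, 0.5, 1e-9),     # symmetry about the center
    ],
)
def test_invert_logistic(target, expected, tol):
    assert invert(CASE1, target) == pytest.approx(expected, abs=tol)


@given(
    a=st.floats(0.5, 1.0),
    b_frac=st.floats(0.3, 1.0),
    k=st.floats(5.0, 40.0),
    s_frac=st.floats(0.05, 0.95),
)
@settings(derandomize=True, max_examples=50)
def test_invert_matches_closed_form_inverse(a, b_frac, k, s_frac):
    """Bisection agrees with the analytic logistic inverse to 1e-9."""
    b = a * b_frac
    curve = LogisticSkillCurve(a=a, b=b, k=k)
    lo, hi = curve.min_success, curve.max_success
    s = lo + s_frac * (hi - lo)
    d_closed = curve.inverse_closed_form(s)
    if not (1e-6 < d_closed < 1 - 1e-6):
        return  # target attained only at/beyond the ends of the unit interval
    assert invert(curve, s) == pytest.approx(d_closed, abs=1e-9)


@given(s_frac=st.floats(0.02, 0.98))
@settings(derandomize=True, max_examples=50)
def test_invert_evaluate_round_trip(s_frac):
    """S(invert(S, s)) = s for interior targets, within bisection tolerance."""
    for curve in (CASE1, CASE2, CASE3):
        lo, hi = curve.min_success, curve.max_success
        s = lo + s_frac * (hi - lo)
        d = invert(curve, s)
        assert curve(d) == pytest.approx(s, abs=1e-6)


def test_invert_step_curve_returns_jump_location():
    curve = StepSkillCurve(theta=0.37, p_high=0.9, p_low=0.3)
    assert invert(curve, 0.6) == pytest.approx(0.37, abs=1e-9)


def test_invert_tabulated_flat_segment_returns_left_edge():
    curve = TabulatedSkillCurve(
        knots=((0.0, 1.0), (0.3, 0.6), (0.7, 0.6), (1.0, 0.0))
    )
    assert invert(curve, 0.6) == pytest.approx(0.3, abs=1e-6)


def test_invert_out_of_range_raises():
    with pytest.raises(ValueError, match="classify_case"):
        invert(CASE2, 0.7)  # max S = 0.6 < 0.7


@pytest.mark.parametrize(
    "curve, target, expected",
    [
        (CASE1, 0.7, INTERIOR),
        (CASE2, 0.7, LOWER_BOUNDARY),   # max S = 0.6 < s*
        (CASE3, 0.7, UPPER_BOUNDARY),   # min S = 0.8 > s*
    ],
)
def test_classify_case(curve, target, expected):
    assert classify_case(curve, target) == expected


def test_validate_monotone():
    assert validate_monotone(CASE1)
    assert validate_monotone(StepSkillCurve(theta=0.5, p_high=0.9, p_low=0.3))
    with pytest.raises(ValueError):
        TabulatedSkillCurve(knots=((0.0, 0.2), (1.0, 0.9)))  # increasing


def test_sample_response_degenerate_and_frequency():
    rng = np.random.default_rng(0)
    always = TabulatedSkillCurve(knots=((0.0, 1.0), (1.0, 1.0)))
    never = TabulatedSkillCurve(knots=((0.0, 0.0), (1.0, 0.0)))
    assert all(sample_response(always, 0.3, rng) == 1 for _ in range(100))
    assert all(sample_response(never, 0.3, rng) == 0 for _ in range(100))

    # Monte-Carlo frequency at S(d)=0.7: within 3 standard errors
    d = invert(CASE1, 0.7)
    n = 100_000
    draws = np.fromiter(
        (sample_response(CASE1, d, rng) for _ in range(n)), dtype=float, count=n
    )
    se = math.sqrt(0.7 * 0.3 / n)
    assert abs(draws.mean() - 0.7) <= 3 * se


def test_curve_from_spec_round_trip():
    curve = curve_from_spec("logistic", a=0.6, b=0.5)
    assert isinstance(curve, LogisticSkillCurve)
    assert curve(0.5) == pytest.approx(0.35)
    tab = curve_from_spec("tabulated", knots=[[0.0, 1.0], [1.0, 0.0]])
    assert tab(0.5) == pytest.approx(0.5)
    with pytest.raises(ValueError, match="unknown skill-curve family"):
        curve_from_spec("cubic")


def test_logistic_parameter_validation():
    with pytest.raises(ValueError):
        LogisticSkillCurve(a=0.5, b=0.6)  # b > a
    with pytest.raises(ValueError):
        LogisticSkillCurve(k=-1.0)
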