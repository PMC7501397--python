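"""Session engine, schedules, convergence measurement, replication."""

import numpy as np
import pytest

from bdtf.core import ControllerConfig, DifficultyState, step
from bdtf.learners import LogisticSkillCurve, TabulatedSkillCurve, invert
from bdtf.simulation import (
    TargetSchedule,
    convergence_time,
    first_hitting_time,
    replicate,
    run_session,
    spawn_seeds,
    terminal_window_size,
    tracking_experiment,
)

CASE1 = LogisticSkillCurve(a=1.0, b=1.0)
ALWAYS = TabulatedSkillCurve(knots=((0.0, 1.0), (1.0, 1.0)))
NEVER = TabulatedSkillCurve(knots=((0.0, 0.0), (1.0, 0.0)))


def test_deterministic_success_chain():
    """S ≡ 1: difficulty climbs by λ(1−s*) each trial until clipping at 1."""
    config = ControllerConfig(lam=0.01, target=0.7, d0=0.5)
    traj = run_session(ALWAYS, config, n_steps=300, seed=0)
    expected = np.minimum(1.0, 0.5 + 0.003 * np.arange(300))
    np.testing.assert_allclose(traj.d, expected, atol=1e-12)
    assert traj.d_end == 1.0


def test_deterministic_failure_chain():
    """S ≡ 0: difficulty falls by λs* each trial until clipping at 0."""
    config = ControllerConfig(lam=0.01, target=0.7, d0=0.5)
    traj = run_session(NEVER, config, n_steps=200, seed=0)
    expected = np.maximum(0.0, 0.5 - 0.007 * np.arange(200))
    np.testing.assert_allclose(traj.d, expected, atol=1e-12)


def test_trajectory_replays_bit_exactly_under_step():
    """Every stored transition satisfies the update rule exactly."""
    config = ControllerConfig(lam=0.01, target=0.7)
    schedule = TargetSchedule(breakpoints=(0, 300), targets=(0.7, 0.9))
    traj = run_session(CASE1, config, schedule, n_steps=600, seed=123)
    state = DifficultyState(t=0, d=config.d0)
    for t in range(len(traj)):
        assert state.d == traj.d[t]
        cfg_t = ControllerConfig(lam=config.lam, target=traj.s_target[t])
        state = step(state, int(traj.x[t]), cfg_t)
    assert state.d == traj.d_end


def test_same_seed_reproduces_same_trajectory():
    config = ControllerConfig(lam=0.01, target=0.7)
    a = run_session(CASE1, config, n_steps=500, seed=7)
    b = run_session(CASE1, config, n_steps=500, seed=7)
    np.testing.assert_array_equal(a.d, b.d)
    np.testing.assert_array_equal(a.x, b.x)


def test_interior_terminal_mean_near_fixed_point():
    """Case-1 long run: last-500 mean within 0.02 of d* = 0.458."""
    config = ControllerConfig(lam=0.01, target=0.7)
    d_star = invert(CASE1, 0.7)
    traj = run_session(CASE1, config, n_steps=5000, seed=11)
    assert traj.d[-500:].mean() == pytest.approx(d_star, abs=0.02)


def test_convergence_time_contract():
    # a trajectory pinned at the limit converges immediately: S≡1 at the top clip
    top = run_session(ALWAYS, ControllerConfig(lam=0.1, target=0.5, d0=1.0),
                      n_steps=50, seed=0)
    assert convergence_time(top, 1.0) == 0
    # a trajectory that never enters the band reports not-converged
    away = run_session(NEVER, ControllerConfig(lam=0.01, target=0.7, d0=1.0),
                       n_steps=20, seed=0)
    assert convergence_time(away, 0.0) is None  # still descending at end
    # a hit with fewer than `window` trials remaining does not count
    assert convergence_time(top, 1.0, window=60) is None


def test_first_hitting_time():
    config = ControllerConfig(lam=0.01, target=0.7, d0=0.5)
    traj = run_session(NEVER, config, n_steps=200, seed=0)
    # monotone descent at 0.007/trial from 0.5 first reaches 0.25 at trial 36
    assert first_hitting_time(traj, 0.25) == 36
    assert first_hitting_time(traj, 0.5) == 0


def test_schedule_validation_and_lookup():
    sch = TargetSchedule(breakpoints=(0, 1500), targets=(0.7, 0.9))
    assert sch.target_at(0) == 0.7
    assert sch.target_at(1499) == 0.7
    assert sch.target_at(1500) == 0.9
    per = sch.per_trial(2000)
    assert per[1499] == 0.7 and per[1500] == 0.9
    with pytest.raises(ValueError):
        TargetSchedule(breakpoints=(1,), targets=(0.7,))
    with pytest.raises(ValueError):
        TargetSchedule(breakpoints=(0, 5), targets=(0.7, 1.0))


def test_replicate_degenerate_single_run():
    config = ControllerConfig(lam=0.01, target=0.7)
    summary = replicate(CASE1, config, n_steps=400, n_replicates=1,
                        base_seed=5, keep_trajectories=True)
    traj = run_session(CASE1, config, n_steps=400, seed=spawn_seeds(5, 1)[0])
    np.testing.assert_array_equal(summary.mean_path, traj.d)
    assert summary.terminal_mean == pytest.approx(traj.d[-100:].mean())


def test_tracking_degenerates_to_plain_session_when_targets_equal():
    traj = tracking_experiment(CASE1, lam=0.01, n_steps=800, switch_t=400,
                               s_before=0.7, s_after=0.7, seed=3)
    plain = run_session(CASE1, ControllerConfig(lam=0.01, target=0.7),
                        n_steps=800, seed=3)
    np.testing.assert_array_equal(traj.d, plain.d)


def test_tracking_moves_to_new_fixed_point():
    traj = tracking_experiment(CASE1, lam=0.01, n_steps=4000, switch_t=1500, seed=2)
    d_before = invert(CASE1, 0.7)
    d_after = invert(CASE1, 0.9)
    assert traj.d[1000:1500].mean() == pytest.approx(d_before, abs=0.03)
    assert traj.d[-400:].mean() == pytest.approx(d_after, abs=0.03)


def test_symmetric_spl_reduction():
    """s* = 0.5 recovers the symmetric scheme: settles where S crosses 50%."""
    config = ControllerConfig(lam=0.01, target=0.5)
    summary = replicate(CASE1, config, n_steps=3000, n_replicates=10, base_seed=1)
    assert summary.terminal_mean == pytest.approx(invert(CASE1, 0.5), abs=0.02)


def test_terminal_window_size_rule():
    assert terminal_window_size(5000) == 500
    assert terminal_window_size(400) == 100
    assert terminal_window_size(50) == 50


def test_lambda_tradeoff_speed_and_oscillation():
    """Bigger λ reaches the limit sooner but oscillates more around it."""
    d_star = invert(CASE1, 0.7)
    medians, spreads = [], []
    for lam, n in ((0.001, 3000), (0.01, 2000), (0.1, 2000)):
        config = ControllerConfig(lam=lam, target=0.7)
        summary = replicate(CASE1, config, n_steps=n, n_replicates=20,
                            base_seed=0, d_star=d_star)
        hits = [h for h in summary.first_hit_times if h is not None]
        medians.append(np.median(hits))
        # steady-state oscillation: dispersion of d in the terminal window
        spreads.append(np.mean(summary.std_path[-100:]))
    assert medians[0] > medians[1] > medians[2]
    assert spreads[0] < spreads[1] < spreads[2]
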