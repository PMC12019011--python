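"""Staircase rule, simulated observer, JND estimation and group statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gvstim.errors import (
    ConfigError,
    InsufficientDataError,
    RunawayError,
    StaircaseStateError,
)
from gvstim.psychophysics import (
    JndEstimate,
    ObserverModel,
    StaircaseConfig,
    convergence_point,
    estimate_jnd,
    initial_state,
    jnd_from_records,
    observer_response,
    run_session,
    staircase_update,
    summarize_group,
    welch_t_test,
)


def brute_force_track(cfg, outcomes):
    """Independent simulator of the verbal 3-down-1-up rule.

    Walks the correctness sequence keeping a plain list of levels and
    reversal levels; no shared code with ``staircase_update``.
    """
    level = cfg.initial_mA
    streak = 0
    last_dir = None
    reversals = []
    levels_seen = []
    for correct in outcomes:
        if len(reversals) >= cfg.reversal_limit:
            break
        levels_seen.append(level)
        direction = None
        if correct:
            streak += 1
            if streak == cfg.down_count:
                direction = -1
                streak = 0
        else:
            direction = +1
            streak = 0
        if direction is not None:
            if last_dir is not None and direction != last_dir:
                reversals.append(level)
            level = min(max(level + direction * cfg.step_mA, cfg.min_mA), cfg.max_mA)
            level = round(level, 12)
            last_dir = direction
    return levels_seen, reversals


class TestStaircaseRule:
    def test_three_down(self):
        cfg = StaircaseConfig()
        state = initial_state(cfg)
        for _ in range(3):
            state = staircase_update(cfg, state, True)
        assert state.level_mA == pytest.approx(1.5)
        assert state.correct_streak == 0

    def test_incorrect_steps_up_and_records_reversal(self):
        cfg = StaircaseConfig()
        state = initial_state(cfg)
        for _ in range(3):
            state = staircase_update(cfg, state, True)  # down to 1.5
        state = staircase_update(cfg, state, False)  # up: direction change
        assert state.level_mA == pytest.approx(1.6)
        assert state.reversal_levels == (pytest.approx(1.5),)

    def test_finishes_at_reversal_limit(self):
        cfg = StaircaseConfig(reversal_limit=2)
        state = initial_state(cfg)
        # down, up(rev 1), down-down-down triple (rev 2)
        for outcome in [True, True, True, False, True, True, True]:
            state = staircase_update(cfg, state, outcome)
        assert state.finished
        with pytest.raises(StaircaseStateError):
            staircase_update(cfg, state, True)

    def test_levels_clamped_to_bounds(self):
        cfg = StaircaseConfig(initial_mA=0.2, min_mA=0.1, max_mA=1.8)
        state = initial_state(cfg)
        for _ in range(6):
            state = staircase_update(cfg, state, True)
        assert state.level_mA >= cfg.min_mA

    @given(st.lists(st.booleans(), min_size=1, max_size=120))
    @settings(max_examples=1000, deadline=None)
    def test_matches_brute_force_rule(self, outcomes):
        """Replaying any correctness sequence equals the verbal-rule oracle."""
        cfg = StaircaseConfig(reversal_limit=4)
        state = initial_state(cfg)
        levels = []
        for outcome in outcomes:
            if state.finished:
                break
            levels.append(state.level_mA)
            state = staircase_update(cfg, state, outcome)
        oracle_levels, oracle_revs = brute_force_track(cfg, outcomes)
        assert levels == pytest.approx(oracle_levels)
        assert list(state.reversal_levels) == pytest.approx(oracle_revs[: cfg.reversal_limit])

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigError):
            StaircaseConfig(step_mA=0.0)
        with pytest.raises(ConfigError):
            StaircaseConfig(max_mA=4.5)
        with pytest.raises(ConfigError):
            StaircaseConfig(reversal_limit=1)


class TestObserver:
    def test_probability_identities(self):
        obs = ObserverModel(threshold_mA=0.7, spread_mA=0.3, lapse_rate=0.0)
        assert obs.p_correct(0.7) == pytest.approx(0.75)  # gamma + 0.5*0.5
        assert obs.p_correct(100.0) == pytest.approx(1.0)
        tight = ObserverModel(threshold_mA=0.7, spread_mA=1e-9, lapse_rate=0.0)
        assert tight.p_correct(0.0) == pytest.approx(0.5)

    def test_response_always_correct_far_above_threshold(self):
        obs = ObserverModel(threshold_mA=0.1, spread_mA=0.01, lapse_rate=0.0)
        rng = np.random.default_rng(0)
        for polarity, expected in ((1, "right"), (-1, "left")):
            assert observer_response(obs, 1.5, polarity, rng) == expected

    def test_analytic_convergence_point(self):
        obs = ObserverModel(threshold_mA=0.7, spread_mA=0.3, lapse_rate=0.02)
        from scipy.stats import norm

        want = 0.7 + 0.3 * norm.ppf((0.5 ** (1 / 3) - 0.5) / 0.48)
        assert obs.analytic_convergence_mA() == pytest.approx(want)


class TestSessions:
    def test_always_correct_observer_descends_monotonically(self):
        cfg = StaircaseConfig(reversal_limit=2, min_mA=0.1)
        obs = ObserverModel(threshold_mA=0.01, spread_mA=1e-6, lapse_rate=0.0)
        with pytest.raises(RunawayError):
            # a perfect observer never reverses except at the clamp, so the
            # track cannot accumulate reversals and hits the cap
            run_session(cfg, obs, seed=0, trial_cap=100)

    def test_same_seed_identical_logs(self):
        cfg = StaircaseConfig()
        obs = ObserverModel(0.7, 0.3)
        a, est_a = run_session(cfg, obs, seed=12)
        b, est_b = run_session(cfg, obs, seed=12)
        assert a == b
        assert est_a == est_b

    def test_session_length_near_reported_scale(self):
        """Sessions with a realistic observer average ~30 trials."""
        cfg = StaircaseConfig()
        obs = ObserverModel(0.7, 0.3, lapse_rate=0.02)
        lengths = [run_session(cfg, obs, seed=s)[1].n_trials for s in range(100)]
        assert 20 < np.mean(lengths) < 60

    def test_intensities_respect_bounds(self):
        cfg = StaircaseConfig()
        obs = ObserverModel(0.3, 0.2, lapse_rate=0.05)
        for seed in range(20):
            records, _ = run_session(cfg, obs, seed=seed)
            intensities = [r.intensity_mA for r in records]
            assert min(intensities) >= cfg.min_mA - 1e-12
            assert max(intensities) <= cfg.max_mA + 1e-12


class TestJndEstimation:
    def test_mean_of_reversals(self):
        est = estimate_jnd([1.5, 1.6, 1.4, 1.5, 1.3, 1.4])
        assert est.jnd_mA == pytest.approx(1.45)
        assert est.n_reversals == 6

    def test_constant_reversals(self):
        assert estimate_jnd([0.7, 0.7, 0.7]).jnd_mA == pytest.approx(0.7)

    def test_last_n_selection(self):
        est = estimate_jnd([9.0, 9.0, 1.0, 1.0], last_n=2)
        assert est.jnd_mA == pytest.approx(1.0)

    def test_too_few_reversals_rejected(self):
        with pytest.raises(InsufficientDataError):
            estimate_jnd([1.0])

    def test_jnd_from_records_uses_reversal_trials(self):
        cfg = StaircaseConfig()
        obs = ObserverModel(0.7, 0.3)
        records, est = run_session(cfg, obs, seed=5)
        # reversal trials carry the pre-step level, matching the estimate
        assert jnd_from_records(records).jnd_mA == pytest.approx(est.jnd_mA)

    def test_parameter_recovery_at_equilibrium(self):
        """Long tracks recover the analytic 79.37%-correct point.

        The mean of post-transient reversal levels over many seeded
        sessions approaches the level where P(correct) = 0.5^(1/3).
        """
        cfg = StaircaseConfig(reversal_limit=12)
        obs = ObserverModel(0.7, 0.3, lapse_rate=0.02)
        jnds = []
        for seed in range(200):
            _, est = run_session(cfg, obs, seed=seed, trial_cap=1000)
            jnds.append(estimate_jnd(est.reversal_levels, last_n=8).jnd_mA)
        assert np.mean(jnds) == pytest.approx(
            obs.analytic_convergence_mA(), abs=0.05
        )

    def test_paper_protocol_has_positive_transient_bias(self):
        """Six reversals from a 1.6 mA start overshoot a 0.7 mA threshold.

        The mean of all six reversal levels includes the initial-descent
        transient, biasing the estimate upward; this is a documented
        property of the short protocol, not an implementation error.
        """
        cfg = StaircaseConfig()
        obs = ObserverModel(0.7, 0.3, lapse_rate=0.02)
        jnds = [run_session(cfg, obs, seed=s)[1].jnd_mA for s in range(200)]
        assert np.mean(jnds) > obs.analytic_convergence_mA() + 0.05


class TestConvergencePoint:
    @pytest.mark.parametrize(
        "down, expected", [(3, 0.5 ** (1 / 3)), (1, 0.5), (2, 0.5**0.5)]
    )
    def test_equilibrium_probability(self, down, expected):
        assert convergence_point(down) == pytest.approx(expected)

    def test_invalid_rule_rejected(self):
        with pytest.raises(ConfigError):
            convergence_point(0)


class TestGroupStats:
    def test_identical_groups(self):
        t, df, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_welch_values(self):
        t, df, p = welch_t_test([1, 2, 3, 4], [2, 3, 4, 5])
        assert t == pytest.approx(-1.0954451)
        assert df == pytest.approx(6.0)

    def test_fractional_df_with_unequal_variances(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.82, 0.46, 7)
        b = rng.normal(0.63, 0.25, 5)
        t, df, p = welch_t_test(a, b)
        assert df != round(df)  # Welch, not pooled: fractional df
        assert 2 < df < 10

    def test_zero_variance_equal_means(self):
        t, df, p = welch_t_test([1.0, 1.0], [1.0, 1.0])
        assert (t, p) == (0.0, 1.0)

    def test_group_summaries(self):
        out = summarize_group([1.0, 2.0, 3.0])
        assert out["all"] == (pytest.approx(2.0), pytest.approx(1.0), 3)
        by_sex = summarize_group([1.0, 2.0, 3.0, 5.0], ["m", "m", "m", "f"])
        assert by_sex["m"][0] == pytest.approx(2.0)
        assert by_sex["f"] == (5.0, 0.0, 1)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            summarize_group([])
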