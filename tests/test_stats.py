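"""Behavioural statistics: optimality, binned curves, partial correlations."""

import numpy as np
import pytest
from scipy import stats as ss

from motorgamble import (
    CohortConfig,
    binned_gamble_rate,
    estimation_error,
    fit_exponential,
    generate_estimation_study,
    optimality_discrepancy,
    partial_spearman,
)
from motorgamble.stats import assign_bin, _rank_residual_corr

from conftest import flat_success_table, make_session


def _ev_session(choices_reward, choices_punishment, p=0.9):
    """Session of reward (EV-diff > 0) and punishment (EV-diff < 0) trials."""
    trials = [
        {"domain": "reward", "certain_value": 10, "success_value": 100,
         "fail_value": 0, "choice": c}
        for c in choices_reward
    ] + [
        {"domain": "punishment", "certain_value": -10, "success_value": 0,
         "fail_value": -100, "choice": c}
        for c in choices_punishment
    ]
    return make_session(trials)


class TestOptimality:
    # flat p = 0.9: reward EV-diff = 90 - 10 = 80 > 0 (gamble optimal);
    # punishment EV-diff = -10 + 10 = 0 is excluded, so use p = 0.8 there
    def test_optimal_chooser_scores_zero(self):
        table = flat_success_table(0.8)
        s = _ev_session([1.0] * 5, [0.0] * 5)
        rew, pun = optimality_discrepancy(s, table)
        assert rew == 0.0 and pun == 0.0

    def test_anti_optimal_chooser_scores_one(self):
        table = flat_success_table(0.8)
        s = _ev_session([0.0] * 5, [1.0] * 5)
        rew, pun = optimality_discrepancy(s, table)
        assert rew == 1.0 and pun == 1.0

    def test_coin_flip_chooser_near_half(self):
        table = flat_success_table(0.8)
        rng = np.random.default_rng(0)
        s = _ev_session(rng.integers(0, 2, 400).astype(float),
                        rng.integers(0, 2, 400).astype(float))
        rew, pun = optimality_discrepancy(s, table)
        assert rew == pytest.approx(0.5, abs=0.07)
        assert pun == pytest.approx(0.5, abs=0.07)

    def test_zero_ev_difference_trials_excluded(self):
        # p = 0.9 makes punishment EV-diff exactly 0: no usable punishment trials
        table = flat_success_table(0.9)
        s = _ev_session([1.0] * 3, [1.0] * 3)
        rew, pun = optimality_discrepancy(s, table)
        assert rew == 0.0
        assert np.isnan(pun)

    def test_invariant_to_trial_order(self):
        table = flat_success_table(0.8)
        s = _ev_session([1.0, 0.0, 1.0], [0.0, 1.0, 0.0])
        shuffled = make_session(
            s.trials.sample(frac=1.0, random_state=1).to_dict("records")
        )
        assert optimality_discrepancy(s, table) == optimality_discrepancy(shuffled, table)


class TestBinning:
    @pytest.mark.parametrize(
        "ev, center", [(-90.0, -85.0), (0.0, 5.0), (-0.001, -5.0), (9.99, 5.0), (10.0, 15.0)]
    )
    def test_half_open_bins_anchored_at_zero(self, ev, center):
        assert assign_bin(ev, 10.0) == center

    def test_all_gamble_gives_rate_one(self):
        table = flat_success_table(0.8)
        s = _ev_session([1.0] * 10, [1.0] * 10)
        curves = binned_gamble_rate([s], table, n_boot=50, seed=0)
        assert (curves["rate"] == 1.0).all()

    def test_rates_match_generator_within_binomial_error(self, small_cohort):
        from motorgamble import estimate_success_table
        from motorgamble.recovery import predicted_curves
        from motorgamble import fit_mle, AA_WINNER

        sessions, truth, surface = small_cohort
        curves = binned_gamble_rate(sessions, surface, n_boot=50, seed=0)
        assert ((curves["rate"] >= 0) & (curves["rate"] <= 1)).all()
        assert (curves["ci_low"] <= curves["rate"]).all()
        assert (curves["rate"] <= curves["ci_high"]).all()


class TestExponentialFit:
    def test_exact_recovery_on_noiseless_curve(self):
        x = np.arange(-90.0, 100.0, 10.0)
        y = -0.5 * np.exp(-0.02 * x) + 0.9
        fit = fit_exponential(x, y)
        assert fit.converged
        assert fit.a == pytest.approx(-0.5, abs=1e-6)
        assert fit.b == pytest.approx(0.02, abs=1e-6)
        assert fit.c == pytest.approx(0.9, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_data_degenerate(self):
        x = np.arange(4.0)
        fit = fit_exponential(x, np.full(4, 0.7))
        assert abs(fit.a) < 1e-6
        assert np.isnan(fit.r_squared)

    def test_small_noise_keeps_r2_near_one(self):
        rng = np.random.default_rng(1)
        x = np.arange(-90.0, 100.0, 10.0)
        y = -0.5 * np.exp(-0.02 * x) + 0.9 + rng.normal(0, 0.005, len(x))
        fit = fit_exponential(x, y)
        assert 0.97 < fit.r_squared < 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential([0, 1, 2], [1, 2, 3])


class TestPartialSpearman:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10)
        age = rng.integers(1, 7, 10).astype(float)
        z = rng.normal(size=(10, 2))
        res = partial_spearman(x, age, z, n_boot=50, n_perm=50, seed=0)
        # oracle: Spearman of least-squares residuals of the ranked variables
        rx, ra = ss.rankdata(x), ss.rankdata(age)
        D = np.column_stack([np.ones(10)] + [ss.rankdata(c) for c in z.T])
        ex = rx - D @ np.linalg.lstsq(D, rx, rcond=None)[0]
        ea = ra - D @ np.linalg.lstsq(D, ra, rcond=None)[0]
        assert res.r == pytest.approx(np.corrcoef(ex, ea)[0, 1], abs=1e-10)

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(4)
        age = rng.integers(1, 7, 30).astype(float)
        z = rng.normal(size=(30, 1))
        res = partial_spearman(age.copy(), age, z, n_boot=50, n_perm=50, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 51)  # add-one floor

    def test_reduces_to_plain_spearman_without_covariates(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        age = x + rng.normal(0, 1.0, 200)
        res = partial_spearman(x, age, None, n_boot=50, n_perm=200, seed=0)
        plain = ss.spearmanr(x, age).statistic
        assert res.r == pytest.approx(plain, abs=1e-10)

    def test_independent_covariates_change_little(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=500)
        age = 0.5 * x + rng.normal(0, 1.0, 500)
        z = rng.normal(size=(500, 2))  # unrelated to both
        res = partial_spearman(x, age, z, n_boot=50, n_perm=100, seed=0)
        plain = ss.spearmanr(x, age).statistic
        assert res.r == pytest.approx(plain, abs=0.05)

    def test_bca_interval_contains_estimate(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            x = rng.normal(size=60)
            age = 0.4 * x + rng.normal(0, 1.0, 60)
            res = partial_spearman(x, age, None, n_boot=300, n_perm=50, seed=seed)
            assert res.ci_low <= res.r <= res.ci_high

    def test_constant_input_flagged(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.ones(10), np.arange(10.0), None, n_boot=5, n_perm=5)


class TestEstimationError:
    @pytest.mark.parametrize(
        "trials, expected", [([(70, 1)], -30.0), ([(0, 0)], 0.0), ([], np.nan)]
    )
    def test_formula(self, trials, expected):
        err = estimation_error(trials)
        assert np.isnan(err) if np.isnan(expected) else err == pytest.approx(expected)

    def test_calibrated_estimator_near_zero(self):
        cfg = CohortConfig()
        study = generate_estimation_study(cfg, n_per_group=10, seed=0)
        trials = list(zip(study["estimate"], study["motor_success"]))
        assert estimation_error(trials) == pytest.approx(0.0, abs=2.5)
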