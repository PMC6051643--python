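"""Maximum-likelihood fitting: likelihood values, estimator API, grid oracle."""

import numpy as np
import pytest
from sklearn.base import clone

from motorgamble import (
    AA_WINNER,
    GambleChoiceModel,
    ModelSpec,
    ParameterVector,
    build_schedule,
    fit_mle,
    grid_oracle,
    log_likelihood,
)
from motorgamble.inference import session_design
from motorgamble.synthetic import simulate_session_choices
from motorgamble.task import session_from_schedule

from conftest import flat_success_table, make_session


@pytest.fixture(scope="module")
def table():
    return flat_success_table(0.5)


def _simulated_session(theta, spec, table, seed, n_blocks=1, pid="S0"):
    """Session with n_blocks x 42 trials simulated from theta."""
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_blocks):
        trials += build_schedule(rng)
    s = session_from_schedule(trials, pid, age_group=2, screen_inches=6.0)
    simulate_session_choices(s, theta, table, rng, spec=spec)
    return s


class TestLogLikelihood:
    def test_chance_prediction_on_full_session(self, table):
        # mu ~ 0 makes every prediction 0.5: logL is 42 ln(1/2)
        s = _simulated_session(
            ParameterVector(alpha=0.8, mu=0.5, delta_plus=0.2, delta_minus=-0.1),
            AA_WINNER, table, seed=0,
        )
        theta = ParameterVector(alpha=0.5, mu=1e-6)
        ll = log_likelihood(theta, ModelSpec(), s, table)
        assert ll == pytest.approx(42 * np.log(0.5), abs=1e-3)

    def test_single_trial_formula(self, table):
        # mu ~ 0 with joint delta 0.3 forces F = 0.8 exactly
        s = make_session([{"choice": 1.0}])
        theta = ParameterVector(alpha=0.5, mu=1e-6, delta=0.3)
        ll = log_likelihood(theta, ModelSpec(delta_mode="joint"), s, table)
        assert ll == pytest.approx(np.log(0.8), abs=1e-5)

    def test_perfect_fit_approaches_zero(self, table):
        s = make_session([{"choice": 1.0} for _ in range(42)])
        theta = ParameterVector(alpha=0.5, mu=1.0, delta=1.0)  # clamps F to 1
        ll = log_likelihood(theta, ModelSpec(delta_mode="joint"), s, table)
        assert -1e-6 < ll <= 0.0

    def test_missing_probability_trials_are_excluded(self):
        sparse = flat_success_table(0.5)
        # remove level-2 cells: those trials must drop out of the likelihood
        sparse.table = sparse.table.drop(
            [k for k in sparse.table.index if k[2] == 2]
        )
        s = make_session(
            [{"choice": 1.0, "target_level": 1}, {"choice": 1.0, "target_level": 2}]
        )
        X, y, n_dropped = session_design(s, sparse)
        assert len(y) == 1 and n_dropped == 1

    def test_all_missing_raises(self):
        empty = flat_success_table(0.5)
        empty.table = empty.table.iloc[0:0]
        s = make_session([{"choice": 1.0}])
        with pytest.raises(ValueError, match="resolvable"):
            session_design(s, empty)


class TestEstimator:
    def test_sklearn_protocol(self, table):
        est = GambleChoiceModel(spec="a1m1d2w0", n_restarts=5, random_state=0)
        params = est.get_params()
        assert params["n_restarts"] == 5
        cloned = clone(est)
        s = _simulated_session(
            ParameterVector(alpha=0.8, mu=0.6, delta_plus=0.2, delta_minus=-0.2),
            AA_WINNER, table, seed=1,
        )
        X, y, _ = session_design(s, table)
        est.fit(X, y)
        proba = est.predict_proba(X)
        assert proba.shape == (42, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert set(est.predict(X)) <= {0, 1}
        assert est.score(X, y) == pytest.approx(est.log_likelihood_ / 42)
        # clone is unfitted but configured identically
        assert not hasattr(cloned, "theta_")
        assert cloned.get_params() == params

    def test_fit_is_deterministic_given_seed(self, table):
        s = _simulated_session(
            ParameterVector(alpha=0.7, mu=0.8, delta_plus=0.3, delta_minus=-0.1),
            AA_WINNER, table, seed=2,
        )
        f1 = fit_mle(s, AA_WINNER, table, n_restarts=8, seed=5)
        f2 = fit_mle(s, AA_WINNER, table, n_restarts=8, seed=5)
        assert f1.log_likelihood == f2.log_likelihood
        assert f1.theta == f2.theta

    def test_fit_beats_null_model(self, table):
        s = _simulated_session(
            ParameterVector(alpha=0.8, mu=0.6, delta_plus=0.2, delta_minus=-0.2),
            AA_WINNER, table, seed=3,
        )
        fit = fit_mle(s, AA_WINNER, table, n_restarts=10, seed=0)
        assert fit.log_likelihood >= 42 * np.log(0.5) - 1e-6
        assert fit.pseudo_r2 >= 0.0
        assert fit.log_likelihood <= 0.0

    def test_nested_model_likelihood_dominance(self, table):
        # data from a delta-free model: AA (joint delta) must fit at least as well
        pt_spec = ModelSpec()
        s = _simulated_session(
            ParameterVector(alpha=0.8, mu=0.6), pt_spec, table, seed=4, n_blocks=4
        )
        pt = fit_mle(s, pt_spec, table, n_restarts=15, seed=1)
        aa = fit_mle(s, ModelSpec(delta_mode="joint"), table, n_restarts=15, seed=1)
        assert aa.log_likelihood >= pt.log_likelihood - 1e-4
        assert abs(aa.theta.delta) < 0.15

    def test_rejects_malformed_inputs(self, table):
        est = GambleChoiceModel(n_restarts=1, random_state=0)
        with pytest.raises(ValueError):
            est.fit(np.ones((5, 3)), np.zeros(5))
        X = np.column_stack([np.full(5, 0.5), np.full(5, 20.0), np.zeros(5),
                             np.full(5, 10.0), np.ones(5)])
        with pytest.raises(ValueError):
            est.fit(X, np.full(5, 2.0))


class TestGridOracle:
    def test_refinement_never_hurts(self, table):
        s = _simulated_session(
            ParameterVector(alpha=0.8, mu=0.6, delta_plus=0.2, delta_minus=-0.2),
            AA_WINNER, table, seed=6,
        )
        coarse = grid_oracle(s, AA_WINNER, table, grid_step=0.25)
        fine = grid_oracle(s, AA_WINNER, table, grid_step=0.125)
        ll_coarse = log_likelihood(coarse, AA_WINNER, s, table)
        ll_fine = log_likelihood(fine, AA_WINNER, s, table)
        assert ll_fine >= ll_coarse - 1e-12

    def test_single_yes_trial_reaches_perfect_fit(self, table):
        # likelihood is monotone in F, so the argmax clamps F to 1 (many ties)
        s = make_session([{"choice": 1.0}])
        spec = ModelSpec(delta_mode="joint")
        theta = grid_oracle(s, spec, table, grid_step=0.25)
        assert theta.delta > 0
        assert log_likelihood(theta, spec, s, table) == pytest.approx(0.0, abs=1e-6)

    def test_misuse_rejected(self, table):
        s = make_session([{"choice": 1.0}])
        with pytest.raises(ValueError, match="4 free"):
            grid_oracle(s, ModelSpec.from_code("a2m2d2w1"), table)
        with pytest.raises(ValueError, match="dense"):
            grid_oracle(s, AA_WINNER, table, grid_step=0.005)
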