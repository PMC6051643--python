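"""Choice-model family: value function, weighting, softmax offsets, enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motorgamble import (
    AA_WINNER,
    PT_WINNER,
    GambleOffer,
    ModelSpec,
    ParameterVector,
    enumerate_models,
    gamble_prob,
    value_fn,
    weight_prob,
)


class TestValueFunction:
    @pytest.mark.parametrize(
        "o, alpha, expected",
        [(10, 0.8, 6.31), (-10, 0.8, -6.31), (20, 0.8, 10.99), (-20, 0.8, -10.99)],
    )
    def test_worked_examples(self, o, alpha, expected):
        assert value_fn(o, alpha) == pytest.approx(expected, abs=5e-3)

    @given(o=st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_identity_at_alpha_one(self, o):
        assert value_fn(o, 1.0) == pytest.approx(o)

    def test_zero_maps_to_zero_and_vectorises(self):
        assert value_fn(0.0, 0.5) == 0.0
        out = value_fn(np.array([-10.0, 0.0, 10.0]), 0.8)
        assert out[0] == -out[2] and out[1] == 0.0

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            value_fn(10, 1.5)
        with pytest.raises(ValueError):
            value_fn(10, 0.5, lam=0.0)


class TestProbabilityWeighting:
    @given(p=st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_gamma_one_is_identity(self, p):
        assert weight_prob(p, 1.0) == pytest.approx(p)

    def test_endpoint_and_example(self):
        assert weight_prob(1.0, 2.0) == pytest.approx(1.0)
        assert weight_prob(0.0, 2.0) == 0.0
        assert weight_prob(0.5, 0.5) == pytest.approx(np.exp(-np.log(2) ** 0.5), abs=1e-4)

    @given(gamma=st.floats(0.2, 3.0))
    @settings(max_examples=30, deadline=None)
    def test_monotone_in_p(self, gamma):
        p = np.linspace(0.001, 1.0, 50)
        w = weight_prob(p, gamma)
        assert np.all(np.diff(w) > 0)


class TestGambleProb:
    def test_half_when_utilities_equal(self):
        theta = ParameterVector(alpha=0.8, mu=1.0)
        spec = ModelSpec()  # joint alpha/mu, no delta, linear
        offer = GambleOffer(1.0, 10, 0, 10)  # certain 10 vs sure-win 10
        assert gamble_prob(offer, theta, spec) == pytest.approx(0.5)

    def test_additive_offset_after_softmax(self):
        theta = ParameterVector(alpha=0.8, mu=1.0, delta=0.2)
        spec = ModelSpec(delta_mode="joint")
        offer = GambleOffer(1.0, 10, 0, 10)
        assert gamble_prob(offer, theta, spec) == pytest.approx(0.7)

    def test_clamped_to_one_when_saturated(self):
        theta = ParameterVector(alpha=1.0, mu=10.0, delta=0.7)
        spec = ModelSpec(delta_mode="joint")
        offer = GambleOffer(1.0, 100, 0, 10)
        assert gamble_prob(offer, theta, spec) == 1.0

    @given(o1=st.integers(11, 99), d=st.floats(-0.3, 0.3))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_success_outcome_and_delta(self, o1, d):
        spec = ModelSpec(delta_mode="joint")
        lo = gamble_prob(GambleOffer(0.5, o1, 0, 10), ParameterVector(alpha=0.8, mu=0.5, delta=0.0), spec)
        hi = gamble_prob(GambleOffer(0.5, o1 + 1, 0, 10), ParameterVector(alpha=0.8, mu=0.5, delta=0.0), spec)
        assert hi >= lo
        shifted = gamble_prob(GambleOffer(0.5, o1, 0, 10), ParameterVector(alpha=0.8, mu=0.5, delta=max(d, 0.0)), spec)
        assert shifted >= lo

    def test_zero_delta_reduces_to_prospect_theory(self):
        pt_theta = ParameterVector(alpha=0.7, mu=0.8)
        aa_theta = ParameterVector(alpha=0.7, mu=0.8, delta=0.0)
        for p in (0.2, 0.5, 0.9):
            for o1, o2, oc in [(60, 0, 10), (0, -60, -10)]:
                offer = GambleOffer(p, o1, o2, oc)
                assert gamble_prob(offer, aa_theta, ModelSpec(delta_mode="joint")) == pytest.approx(
                    gamble_prob(offer, pt_theta, ModelSpec())
                )

    def test_null_parameters_predict_chance(self):
        # the pseudo-R2 null: no value sensitivity, no bias -> F = 0.5 always
        theta = ParameterVector(alpha=0.0, mu=1e-6, delta=0.0)
        spec = ModelSpec(delta_mode="joint")
        for offer in [GambleOffer(0.3, 100, 0, 10), GambleOffer(0.9, 0, -100, -10)]:
            assert gamble_prob(offer, theta, spec) == pytest.approx(0.5, abs=1e-5)

    def test_split_delta_creates_reward_punishment_gap_at_equal_ev(self):
        theta = ParameterVector(alpha=0.8, mu=0.5, delta_plus=0.2, delta_minus=-0.2)
        # EV-matched offers: both have EV_gamble == EV_certain
        reward = GambleOffer(0.5, 20, 0, 10)
        punishment = GambleOffer(0.5, 0, -20, -10)
        f_r = gamble_prob(reward, theta, AA_WINNER)
        f_p = gamble_prob(punishment, theta, AA_WINNER)
        assert f_r > f_p


class TestEnumeration:
    def test_twenty_four_unique_models(self):
        specs = enumerate_models()
        assert len(specs) == 24
        assert len({s.code for s in specs}) == 24
        assert AA_WINNER in specs and PT_WINNER in specs

    def test_twelve_linear_models(self):
        linear = [s for s in enumerate_models() if s.weighting == "linear"]
        assert len(linear) == 12

    @pytest.mark.parametrize(
        "code, k",
        [("a1m1d0w0", 2), ("a1m1d2w0", 4), ("a2m2d0w0", 4), ("a2m2d2w1", 7)],
    )
    def test_parameter_counts(self, code, k):
        assert ModelSpec.from_code(code).k == k

    def test_code_round_trip(self):
        for spec in enumerate_models():
            assert ModelSpec.from_code(spec.code) == spec

    def test_winning_model_codes(self):
        assert AA_WINNER.code == "a1m1d2w0"
        assert AA_WINNER.param_names == ("alpha", "mu", "delta_plus", "delta_minus")
        assert PT_WINNER.param_names == ("alpha_plus", "alpha_minus", "mu_plus", "mu_minus")


class TestParameterVector:
    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            ParameterVector(alpha=1.2, mu=1.0)
        with pytest.raises(ValueError):
            ParameterVector(alpha=0.5, mu=11.0)
        with pytest.raises(ValueError):
            ParameterVector(alpha=0.5, mu=1.0, delta=-1.5)
        with pytest.raises(ValueError):
            ParameterVector(alpha=0.5, mu=1.0, lam=2.0)

    def test_array_round_trip(self):
        theta = ParameterVector(alpha=0.8, mu=0.5, delta_plus=0.3, delta_minus=-0.2)
        x = theta.to_array(AA_WINNER)
        assert ParameterVector.from_array(AA_WINNER, x) == theta

    def test_domain_selection(self):
        theta = ParameterVector(alpha=0.8, mu=0.5, delta_plus=0.3, delta_minus=-0.2)
        assert theta.for_domain(+1)[2] == 0.3
        assert theta.for_domain(-1)[2] == -0.2
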