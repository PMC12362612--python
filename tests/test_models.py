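"""Model library: factories, right-hand sides, reaction/ODE equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fatebias as fb
from fatebias.models import ControllerConfig, ModelError
from fatebias.params import ParameterError


# fixed-point oracle: iterate y1 = a1/(1+y2^m), y2 = a2/(1+y1^m)
def _toggle_fixed_point(a1, a2, m=3, y0=(2.2, 0.0), iters=200):
    y1, y2 = y0
    for _ in range(iters):
        y1, y2 = a1 / (1 + y2 ** m), a2 / (1 + y1 ** m)
    return y1, y2


class TestToggleFactory:
    def test_rhs_at_origin_equals_max_production(self, toggle):
        np.testing.assert_allclose(toggle.rhs([0, 0]), [2.2, 2.2])

    def test_rhs_vanishes_at_iterated_fixed_point(self, toggle):
        y = _toggle_fixed_point(2.2, 2.2)
        assert np.max(np.abs(toggle.rhs(y))) < 1e-8
        np.testing.assert_allclose(y, (2.1844, 0.1926), atol=1e-3)

    def test_symmetric_swap_commutes(self, toggle):
        y = np.array([0.7, 1.9])
        f = toggle.rhs(y)
        f_swapped = toggle.rhs(y[::-1])
        np.testing.assert_allclose(f[::-1], f_swapped)

    def test_invalid_params_name_the_field(self):
        with pytest.raises(ParameterError, match="delta"):
            fb.KineticParams(delta=0.0)
        with pytest.raises(ParameterError, match="m"):
            fb.KineticParams(m=0)
        with pytest.raises(ParameterError, match="gamma"):
            fb.KineticParams(gamma=-1)

    def test_scaling_covariance_of_hill_kinetics(self, nominal):
        # doubling K and the production rates reproduces doubled kinetics
        big = fb.make_toggle(nominal.replace(alpha1=4.4, alpha2=4.4, K=2.0))
        small = fb.make_toggle(nominal)
        y = np.array([0.37, 1.41])
        np.testing.assert_allclose(big.rhs(2 * y), 2 * small.rhs(y), rtol=1e-12)


class TestIsolatedController:
    def test_zero_input_rests_at_origin(self, nominal):
        spec = fb.make_isolated_controller(nominal, lambda t: 0.0)
        np.testing.assert_allclose(spec.rhs([0, 0, 0]), [0, 0, 0])

    def test_constant_input_steady_state(self, nominal):
        spec = fb.make_isolated_controller(nominal, lambda t: 1.0)
        # x̄ = θ/δ = 1; ū1 from the sequestration quadratic
        u1, u2, x = fb.controller_qss(1.0, nominal)
        assert x == pytest.approx(1.0)
        assert u1 == pytest.approx((-1 + np.sqrt(401)) / 200, abs=1e-12)
        assert np.max(np.abs(spec.rhs([x, u1, u2]))) < 1e-12

    def test_negative_input_rejected(self, nominal):
        spec = fb.make_isolated_controller(nominal, lambda t: -1.0)
        with pytest.raises(ModelError):
            spec.rhs([0.0, 0.0, 0.0], t=1.0)


class TestControlledToggle:
    def test_zero_gain_reduces_to_isolated_toggle(self, nominal, toggle):
        spec = fb.make_controlled_toggle(nominal.replace(beta=0.0))
        y = np.array([0.9, 1.3])
        state = np.array([y[0], y[1], 0.2, 0.4, 0.6])
        np.testing.assert_allclose(spec.rhs(state)[:2],
                                   toggle.rhs(y) + [0.0, 0.0], atol=0)
        # identical endogenous flux irrespective of controller state
        state2 = np.array([y[0], y[1], 2.0, 1.0, 0.1])
        np.testing.assert_allclose(spec.rhs(state2)[:2], spec.rhs(state)[:2])

    def test_qss_control_boost_at_toggle_equilibrium(self, nominal, controlled_neg):
        # at the Y1-high toggle equilibrium the sensing Hill is p2(2.1844);
        # the QSS controller output gives u1 = 0.0250
        y = _toggle_fixed_point(2.2, 2.2)
        p2 = 1.0 / (1.0 + y[0] ** 3)
        u1, u2, x = fb.controller_qss(p2, nominal)
        assert u1 == pytest.approx(0.0250, abs=1e-3)
        state = np.array([y[0], y[1], x, u1, u2])
        boost = controlled_neg.rhs(state)[0]
        assert boost == pytest.approx(nominal.beta * u1, abs=1e-9)

    def test_u2_input_differs_in_exactly_one_term(self, nominal):
        u1_spec = fb.make_controlled_toggle(nominal, ControllerConfig(input_species="U1"))
        u2_spec = fb.make_controlled_toggle(nominal, ControllerConfig(input_species="U2"))
        diff = set(u1_spec.terms) ^ set(u2_spec.terms)
        assert len(diff) == 2  # one term swapped for its U2 twin
        kinds = {t.kind for t in diff}
        assert kinds == {"additive_control"}

    def test_double_requires_beta_prime(self, nominal):
        with pytest.raises(ModelError, match="beta_prime"):
            fb.make_controlled_toggle(nominal, ControllerConfig(duplicated="double"))
        spec = fb.make_controlled_toggle(nominal.replace(beta_prime=1.0),
                                         ControllerConfig(sense_species="Y2",
                                                          duplicated="double"))
        assert spec.n_species == 8
        assert {c.target_species for c in spec.controllers} == {"Y1", "Y2"}


class TestSelfActivationAndMutualActivation:
    def test_zero_alpha3_matches_plain_toggle(self, nominal, toggle):
        spec = fb.make_toggle_selfactivation(nominal.replace(alpha3=0.0))
        y = np.array([1.7, 0.2])
        np.testing.assert_allclose(spec.rhs(y), toggle.rhs(y))

    def test_diagonal_fixed_point_of_double_selfactivation(self):
        # on the diagonal the repressing and activating Hill terms sum to 1
        spec = fb.make_toggle_selfactivation(fb.tristable_params(), double=True)
        np.testing.assert_allclose(spec.rhs([1.2, 1.2]), [0.0, 0.0], atol=1e-14)

    def test_mutual_activation_origin_and_high_state(self, mutual_activation):
        np.testing.assert_allclose(mutual_activation.rhs([0, 0]), [0, 0])
        # symmetric high state: largest root of y^3 - 2.2 y^2 + 1 = 0
        roots = np.roots([1.0, -2.2, 0.0, 1.0])
        y_high = max(r.real for r in roots if abs(r.imag) < 1e-12)
        assert np.max(np.abs(mutual_activation.rhs([y_high, y_high]))) < 1e-9

    def test_controlled_mutual_activation_rests_at_origin(self, nominal):
        spec = fb.make_controlled_mutual_activation(nominal)
        np.testing.assert_allclose(spec.rhs(np.zeros(5)), np.zeros(5))

    def test_controlled_mutual_activation_rejects_additive(self, nominal):
        with pytest.raises(ModelError, match="degradation"):
            fb.make_controlled_mutual_activation(
                nominal, ControllerConfig(sense_species="Y1",
                                          sense_regulation="activating",
                                          actuation="additive_activation"))


class TestControlledTristable:
    def test_zero_gains_reduce_to_double_selfactivation(self, tristable_base):
        params = fb.tristable_params(beta=0.0, beta_prime=0.0)
        spec = fb.make_controlled_tristable(params)
        y = np.array([0.8, 1.6])
        state = np.zeros(8)
        state[:2] = y
        state[3] = 0.3  # nonzero U1 must not leak into y-dot at zero gain
        np.testing.assert_allclose(spec.rhs(state)[:2], tristable_base.rhs(y))

    def test_double_inhibition_term_structure(self):
        spec = fb.make_controlled_tristable(fb.tristable_params(beta_prime=1.0))
        mm = [t for t in spec.terms if t.kind == "mm_degradation_control"]
        assert {(t.target, t.source) for t in mm} == {("Y1", "U1"), ("Y2", "U1p")}

    def test_mixed_strategy_term_structure(self):
        from fatebias.models import default_tristable_config
        cfg1 = default_tristable_config("Y1", actuation="additive_activation")
        cfg2 = default_tristable_config("Y2")
        spec = fb.make_controlled_tristable(fb.tristable_params(beta_prime=1.0),
                                            cfg1, cfg2)
        adds = [t for t in spec.terms if t.kind == "additive_control"]
        mms = [t for t in spec.terms if t.kind == "mm_degradation_control"]
        assert [(t.target, t.source) for t in adds] == [("Y1", "U1")]
        assert [(t.target, t.source) for t in mms] == [("Y2", "U1p")]
        # additive actuation is driven by repressing sensing of the target
        assert spec.controllers[0].sense_regulation == "repressing"
        assert spec.controllers[1].sense_regulation == "activating"


ALL_SPECS = ["toggle", "controlled_neg", "controlled_pos", "mutual_activation",
             "tristable_base", "controlled_tristable"]


def _spec_by_name(request, name):
    if name == "controlled_tristable":
        return fb.make_controlled_tristable(fb.tristable_params(beta_prime=1.0))
    return request.getfixturevalue(name)


class TestReactions:
    def test_toggle_channel_count(self, toggle):
        rxns = fb.reactions(toggle)
        assert len(rxns) == 4  # 2 production + 2 decay

    def test_controlled_toggle_channel_count(self, controlled_neg):
        # 4 Hill productions (Y1, Y2, X, U2) + catalytic U1 production
        # + adaptive-control channel + 5 decays + 1 sequestration
        rxns = fb.reactions(controlled_neg)
        kinds = [r.term.kind for r in rxns]
        assert len(rxns) == 12
        assert kinds.count("hill_production") == 4
        assert kinds.count("linear_decay") == 5
        assert kinds.count("sequestration") == 1
        assert kinds.count("additive_control") == 1

    def test_sequestration_removes_both_partners_equally(self, controlled_neg):
        seq = [r for r in fb.reactions(controlled_neg)
               if r.term.kind == "sequestration"][0]
        i1 = controlled_neg.index("U1")
        i2 = controlled_neg.index("U2")
        assert seq.stoichiometry[i1] == seq.stoichiometry[i2] == -1

    @pytest.mark.parametrize("name", ALL_SPECS)
    def test_reaction_drift_equals_rhs(self, request, name):
        """Σ stoichiometry × propensity reproduces the ODE right-hand side."""
        spec = _spec_by_name(request, name)
        rxns = fb.reactions(spec)
        rng = np.random.default_rng(12345)
        for _ in range(100):
            state = rng.uniform(0, 3, spec.n_species)
            drift = sum(r.stoichiometry * r.propensity(state) for r in rxns)
            np.testing.assert_allclose(drift, spec.rhs(state), atol=1e-12)

    def test_propensities_nonnegative_on_random_states(self, controlled_neg):
        rng = np.random.default_rng(7)
        for r in fb.reactions(controlled_neg):
            for _ in range(20):
                assert r.propensity(rng.uniform(0, 5, 5)) >= 0


class TestRhsValidation:
    def test_rejects_nan_and_negative_state(self, toggle):
        with pytest.raises(ModelError):
            toggle.rhs([np.nan, 0.0])
        with pytest.raises(ModelError):
            toggle.rhs([-0.1, 0.0])

    def test_undeclared_species_in_term_rejected(self, nominal):
        from fatebias.models import ModelSpec, Term
        with pytest.raises(ModelError, match="undeclared"):
            ModelSpec("bad", ("Y1",), nominal,
                      (Term("linear_decay", "Y2", 1.0),))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(y1=st.floats(0, 5), y2=st.floats(0, 5),
       beta=st.floats(0, 4), gamma=st.floats(0.1, 1000))
def test_controlled_toggle_drift_identity_property(y1, y2, beta, gamma):
    """Reaction-derived drift ≡ rhs for arbitrary states and gains."""
    params = fb.nominal_params(beta=beta, gamma=gamma)
    spec = fb.make_controlled_toggle(params)
    state = np.array([y1, y2, 0.5 * y1, 0.2, 0.1])
    drift = sum(r.stoichiometry * r.propensity(state) for r in fb.reactions(spec))
    np.testing.assert_allclose(drift, spec.rhs(state), atol=1e-12)


@pytest.mark.parametrize("name", ALL_SPECS)
def test_forward_invariance_from_random_starts(request, name):
    """Trajectories from random nonnegative starts never leave the orthant."""
    spec = _spec_by_name(request, name)
    rng = np.random.default_rng(99)
    for _ in range(12):
        x0 = rng.uniform(0, 3, spec.n_species)
        traj = fb.simulate_ode(spec, x0, 30.0, n_points=300)
        assert traj.states.min() >= -1e-9
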