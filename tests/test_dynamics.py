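"""Unit and property tests for the point-neuron dynamics and learning rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microzone.params import ChannelParams, ChannelSet, DynamicsParams
from microzone.state import LayerState, NetworkState, ProjectionState, EXCITATORY
from microzone import dynamics
from microzone.dynamics import (
    NumericalStateError, SettlingError, cpca_delta, generec_delta,
    kwta_inhibition, rate_activation, settle, step_membrane,
)

CH = ChannelSet()


# ---------------------------------------------------------------------------
# membrane update
# ---------------------------------------------------------------------------

class TestStepMembrane:
    def test_no_driving_current_leaves_potential_unchanged(self):
        v = 0.42
        out = step_membrane(v, {"excitatory": 0.0, "inhibitory": 0.0, "leak": 0.0}, CH)
        assert out == pytest.approx(v, abs=0.0)

    def test_reversal_potential_is_a_fixed_point(self):
        out = step_membrane(CH.excitatory.e_rev, {"excitatory": 0.7}, CH)
        assert out == pytest.approx(CH.excitatory.e_rev, abs=1e-15)

    def test_weighted_average_of_reversals_is_fixed_point(self):
        g = {"excitatory": 0.3, "inhibitory": 0.2, "leak": 1.0}
        num = (0.3 * CH.excitatory.g_bar * CH.excitatory.e_rev
               + 0.2 * CH.inhibitory.g_bar * CH.inhibitory.e_rev
               + 1.0 * CH.leak.g_bar * CH.leak.e_rev)
        den = (0.3 * CH.excitatory.g_bar + 0.2 * CH.inhibitory.g_bar
               + 1.0 * CH.leak.g_bar)
        v_star = num / den
        out = step_membrane(v_star, g, CH)
        assert abs(out - v_star) < 1e-12

    def test_single_channel_relaxation_matches_closed_form(self):
        # independent oracle: the one-channel update is linear,
        # V_t = E + (1 - tau*g*gbar)^t (V_0 - E)
        params = DynamicsParams(tau=0.2)
        g, v0 = 0.8, 0.3
        rate = params.tau * g * CH.excitatory.g_bar
        v = v0
        for t in range(1, 40):
            v = step_membrane(v, {"excitatory": g}, CH, params)
            expected = CH.excitatory.e_rev + (1 - rate) ** t * (v0 - CH.excitatory.e_rev)
            assert abs(v - expected) < 1e-9

    @settings(deadline=None, max_examples=60)
    @given(
        v0=st.floats(0.15, 1.0),
        ge=st.floats(0, 50), gi=st.floats(0, 50), gl=st.floats(0, 50),
        steps=st.integers(1, 30),
    )
    def test_membrane_always_bounded_by_reversal_range(self, v0, ge, gi, gl, steps):
        v = v0
        for _ in range(steps):
            v = step_membrane(v, {"excitatory": ge, "inhibitory": gi, "leak": gl}, CH)
        assert CH.e_min <= v <= CH.e_max

    def test_non_finite_conductance_raises_with_unit_index(self):
        with pytest.raises(NumericalStateError):
            step_membrane(np.array([0.3, 0.3]),
                          {"excitatory": np.array([0.1, np.nan])}, CH)
        with pytest.raises(NumericalStateError):
            step_membrane(np.array([np.inf, 0.3]), {"excitatory": 0.1}, CH)


# ---------------------------------------------------------------------------
# rate activation
# ---------------------------------------------------------------------------

class TestRateActivation:
    def test_subthreshold_is_exactly_zero(self):
        p = DynamicsParams()
        assert rate_activation(p.threshold - 0.2, p) == 0.0
        assert rate_activation(p.threshold, p) == 0.0

    @settings(deadline=None, max_examples=60)
    @given(v1=st.floats(0.0, 1.0), v2=st.floats(0.0, 1.0),
           gain=st.floats(0.5, 500))
    def test_monotone_in_membrane_potential(self, v1, v2, gain):
        p = DynamicsParams(gain=gain)
        lo, hi = sorted((v1, v2))
        assert rate_activation(lo, p) <= rate_activation(hi, p)

    def test_large_gain_saturates_toward_one(self):
        p = DynamicsParams(gain=1e7)
        assert rate_activation(p.threshold + 0.01, p) > 0.999

    def test_output_bounded_in_unit_interval(self):
        p = DynamicsParams(gain=100)
        for v in np.linspace(0, 1, 21):
            assert 0.0 <= rate_activation(v, p) < 1.0


# ---------------------------------------------------------------------------
# kWTA
# ---------------------------------------------------------------------------

def _equilibrium_v(ge, gi, ch=CH):
    num = (ge * ch.excitatory.g_bar * ch.excitatory.e_rev
           + ch.leak.g_bar * ch.leak.e_rev
           + gi * ch.inhibitory.g_bar * ch.inhibitory.e_rev)
    den = ge * ch.excitatory.g_bar + ch.leak.g_bar + gi * ch.inhibitory.g_bar
    return num / den


class TestKwta:
    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("k", [1, 2, 4, 7])
    def test_supra_threshold_set_matches_sort_oracle(self, seed, k):
        """On layers of <= 10 units with distinct drives, exactly the top-k
        (by a brute-force sort) can exceed threshold at equilibrium."""
        rng = np.random.default_rng(seed)
        n = 10
        layer = LayerState(name="toy", n=n, k=k)
        p = DynamicsParams(gain=100)
        ge = rng.uniform(0.1, 2.0, size=(1, n))
        gi = kwta_inhibition(layer, ge, np.zeros_like(ge), CH, p)
        v_eq = _equilibrium_v(ge, gi)
        supra = set(np.flatnonzero(v_eq[0] > p.threshold))
        oracle = set(np.argsort(-ge[0], kind="stable")[:k])
        assert supra == oracle

    def test_k_at_least_layer_size_suppresses_nothing(self):
        layer = LayerState(name="toy", n=5, k=5)
        ge = np.array([[0.5, 1.0, 0.2, 0.8, 0.3]])
        gi = kwta_inhibition(layer, ge, np.zeros_like(ge), CH, DynamicsParams())
        assert np.all(gi == 0.0)

    def test_k_zero_silences_every_unit(self):
        layer = LayerState(name="toy", n=4, k=0)
        p = DynamicsParams(gain=100)
        ge = np.array([[0.5, 1.0, 0.2, 0.8]])
        gi = kwta_inhibition(layer, ge, np.zeros_like(ge), CH, p)
        v_eq = _equilibrium_v(ge, gi)
        assert np.all(rate_activation(v_eq, p) == 0.0)

    def test_lesioned_units_excluded_from_competition(self):
        layer = LayerState(name="toy", n=4, k=1)
        layer.lesioned[1] = True  # the strongest unit is dead
        p = DynamicsParams(gain=100)
        ge = np.array([[0.5, 2.0, 0.2, 0.8]])
        gi = kwta_inhibition(layer, ge, np.zeros_like(ge), CH, p)
        v_eq = _equilibrium_v(ge, gi)
        supra = set(np.flatnonzero(v_eq[0] > p.threshold)) - {1}
        assert supra == {3}  # strongest live unit wins


# ---------------------------------------------------------------------------
# settling
# ---------------------------------------------------------------------------

def _two_layer_net(w, sign=EXCITATORY, strength=1.0, gain=20.0, cycles=300):
    inp = LayerState(name="in", n=2, role="input", kwta=False)
    out = LayerState(name="out", n=2, role="output", kwta=False)
    proj = ProjectionState(
        source="in", target="out", sign=sign, strength=strength,
        weights=np.asarray(w, dtype=np.float64),
        divisor=np.full(2, 2 * 0.5),
    )
    return NetworkState(
        layers={"in": inp, "out": out}, projections=[proj],
        dynamics=DynamicsParams(gain=gain, cycles=cycles, settle_tol=0.0),
        dtype=np.float64,
    )


class TestSettle:
    def test_zero_input_zero_bias_gives_silent_network(self, micro_config):
        from microzone import build_microzone
        net = build_microzone(micro_config, seed=0)
        clamps = {"mossy_fibers": np.zeros(24), "climbing_fibers": np.zeros(3)}
        settle(net, clamps, phase="minus")
        for name, layer in net.layers.items():
            if name in clamps:
                continue
            assert np.allclose(layer.y_minus, 0.0, atol=1e-6), name

    def test_clamped_layer_holds_values_exactly(self, micro_config):
        from microzone import build_microzone
        net = build_microzone(micro_config, seed=0)
        mossy = np.random.default_rng(0).uniform(0, 1, 24)
        climbing = np.array([1.0, 0.0, 1.0])
        settle(net, {"mossy_fibers": mossy, "climbing_fibers": climbing}, "minus")
        assert np.array_equal(
            net.layer("mossy_fibers").y_minus[0], mossy.astype(net.dtype))
        assert np.array_equal(
            net.layer("climbing_fibers").y_minus[0], climbing.astype(net.dtype))

    def test_two_layer_equilibrium_matches_fixed_point_oracle(self):
        # independent oracle: iterate the exact equilibrium map to convergence
        w = np.array([[0.9, 0.2], [0.3, 0.7]])
        x = np.array([0.8, 0.4])
        net = _two_layer_net(w)
        settle(net, {"in": x}, phase="minus")
        got = net.layer("out").y_minus[0]

        p, ch = net.dynamics, net.channels
        ge = (x @ w) / 1.0  # strength/divisor = 1
        v = _equilibrium_v(ge, 0.0, ch)
        expect = np.maximum(p.gain * (v - p.threshold), 0)
        expect = expect / (expect + 1)
        assert np.allclose(got, expect, atol=1e-6)

    def test_unknown_clamp_group_raises(self, micro_config):
        from microzone import build_microzone
        net = build_microzone(micro_config, seed=0)
        with pytest.raises(KeyError):
            settle(net, {"nonexistent": np.zeros(3)}, "minus")

    def test_non_finite_state_raises_settling_error_with_cycle(self):
        net = _two_layer_net(np.full((2, 2), 0.5))
        net.layer("out").bias = np.array([np.nan, 0.0])
        with pytest.raises((SettlingError, NumericalStateError)):
            settle(net, {"in": np.ones(2)}, "minus")


# ---------------------------------------------------------------------------
# learning rules
# ---------------------------------------------------------------------------

class TestLearningRules:
    def test_cpca_zero_when_weight_equals_input(self):
        assert cpca_delta(0.6, 0.9, 0.6, 0.1) == 0.0

    def test_cpca_zero_for_inactive_receiver(self):
        assert cpca_delta(0.8, 0.0, 0.2, 0.1) == 0.0

    def test_cpca_direct_value(self):
        assert cpca_delta(1.0, 1.0, 0.25, 0.1) == pytest.approx(0.075)

    @settings(deadline=None, max_examples=60)
    @given(x=st.floats(0, 1), y=st.floats(0, 1), w=st.floats(0, 1),
           eps=st.floats(0, 1))
    def test_cpca_keeps_weights_bounded(self, x, y, w, eps):
        assert 0.0 <= w + cpca_delta(x, y, w, eps) <= 1.0

    def test_generec_zero_when_phases_agree(self):
        assert generec_delta(0.3, 0.7, 0.3, 0.7, 0.1) == 0.0

    def test_generec_direct_value(self):
        assert generec_delta(0.2, 0.5, 0.8, 0.5, 0.1) == pytest.approx(0.03)

    def test_generec_negative_when_expectation_exceeds_outcome(self):
        assert generec_delta(0.9, 0.9, 0.1, 0.1, 0.1) < 0.0

    @settings(deadline=None, max_examples=60)
    @given(xm=st.floats(0, 1), ym=st.floats(0, 1),
           xp=st.floats(0, 1), yp=st.floats(0, 1), eps=st.floats(0, 1))
    def test_generec_phase_swap_negates_exactly(self, xm, ym, xp, yp, eps):
        assert generec_delta(xm, ym, xp, yp, eps) == -generec_delta(xp, yp, xm, ym, eps)


class TestApplyLearning:
    def test_network_update_matches_elementwise_rules(self):
        """Dual route: the vectorized update must equal the scalar CPCA and
        GeneRec formulas applied element by element."""
        net = _two_layer_net(np.array([[0.5, 0.4], [0.6, 0.3]]))
        net.learning.hebb = 0.3
        net.learning.lrate = 0.1
        net.learning.bias_lrate = 0.0
        p = net.projections[0]
        p.lrate = 0.1
        xm, ym = np.array([[0.8, 0.1]]), np.array([[0.5, 0.2]])
        xp, yp = np.array([[0.8, 0.1]]), np.array([[0.9, 0.0]])
        net.layer("in").y_minus, net.layer("in").y_plus = xm, xp
        net.layer("out").y_minus, net.layer("out").y_plus = ym, yp
        w0 = p.weights.copy()
        dynamics.apply_learning(net)
        lam = 0.3
        for i in range(2):
            for j in range(2):
                expected = (
                    (1 - lam) * generec_delta(xm[0, i], ym[0, j], xp[0, i], yp[0, j], 0.1)
                    + lam * cpca_delta(xp[0, i], yp[0, j], w0[i, j], 0.1)
                )
                assert p.weights[i, j] == pytest.approx(w0[i, j] + expected, abs=1e-12)

    def test_zero_learning_rate_is_bitwise_noop(self, micro_config):
        import copy
        from microzone import build_microzone, generate_training_set, train_to_criterion
        cfg = copy.deepcopy(micro_config)
        cfg.learning.lrate = 0.0
        cfg.learning.bias_lrate = 0.0
        net = build_microzone(cfg, seed=3)
        for proj in net.projections:
            proj.lrate = 0.0
        tset = generate_training_set(cfg, seed=5)
        before = net.weight_snapshot()
        result = train_to_criterion(net, tset, max_epochs=2)
        assert not result.converged
        errs = [r.error_pct for r in result.records]
        assert errs[0] == errs[1]
        after = net.weight_snapshot()
        for key, w in before.items():
            if key == "__bias__":
                for name, b in w.items():
                    assert np.array_equal(b, after["__bias__"][name])
            else:
                assert np.array_equal(w, after[key])
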