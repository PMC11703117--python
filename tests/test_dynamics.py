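"""Unit tests for the neuron/synapse equations and the RK4 core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from cxheading import (
    CircuitDynamics,
    DegenerateCircuitError,
    ModelConstants,
    firing_rate,
    release_derivative,
    steady_state_potential,
    synapse_derivative,
    synapse_fixed_point,
    total_conductance,
)

C = ModelConstants()


class TestFiringRate:
    def test_midpoint_gives_half_maximum(self):
        assert firing_rate(C.half_point) == pytest.approx(C.r_max / 2.0)

    def test_lower_asymptote(self):
        assert firing_rate(-1e6) == pytest.approx(0.0, abs=1e-12)
        assert firing_rate(1e6) == pytest.approx(C.r_max)

    def test_matches_independent_scalar_evaluation_at_zero(self):
        # independent evaluation of the logistic law with plain Python floats
        import math

        expected = 99.6 / (1.0 + math.exp(0.19 * 17.8))
        assert firing_rate(0.0) == pytest.approx(expected, rel=1e-12)

    def test_rejects_non_finite_input(self):
        with pytest.raises(ValueError):
            firing_rate(float("nan"))
        with pytest.raises(ValueError):
            firing_rate(np.inf)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-100.0, 50.0), st.floats(0.001, 50.0))
    def test_strictly_monotone_and_bounded(self, u, du):
        lo, hi = firing_rate(u), firing_rate(u + du)
        assert 0.0 < lo < hi < C.r_max


class TestTotalConductance:
    def test_unmodulated_limits(self):
        assert total_conductance(2.5, [0.3, -0.4], [0.0, 0.0]) == pytest.approx(2.5)
        assert total_conductance(2.5, [0.0, 0.0], [1.0, 0.5]) == pytest.approx(2.5)

    def test_linear_combination(self):
        assert total_conductance(1.0, [0.5, -0.5], [1.0, 0.0]) == pytest.approx(1.5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_conductance(1.0, [0.5, 0.5], [1.0])

    def test_out_of_range_release_rejected(self):
        with pytest.raises(ValueError):
            total_conductance(1.0, [0.5], [1.5])


class TestSteadyStatePotential:
    def test_empty_sum_rests_at_zero(self):
        assert steady_state_potential([], [], []) == 0.0

    def test_shunting_saturation_at_reversal_potential(self):
        assert steady_state_potential([1e9], [1.0], [60.0]) == pytest.approx(
            60.0, rel=1e-6
        )

    def test_single_input_value(self):
        # 1 * 0.5 * 60 / (1 + 0.5) = 20
        assert steady_state_potential([1.0], [0.5], [60.0]) == pytest.approx(20.0)

    def test_degenerate_denominator_raises(self):
        with pytest.raises(DegenerateCircuitError):
            steady_state_potential([-2.0], [0.5], [60.0])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 5.0), min_size=1, max_size=8))
    def test_convex_hull_for_nonnegative_conductances(self, gs):
        # with one reversal potential, U must lie between rest and E_ex
        p = np.full(len(gs), 0.7)
        e = np.full(len(gs), 60.0)
        u = steady_state_potential(gs, p, e)
        assert 0.0 <= u <= 60.0


class TestSynapseKinetics:
    def test_pure_decay_at_zero_rate(self):
        assert synapse_derivative(0.4, 0.0) == pytest.approx(-0.4 / C.tau_s)

    def test_empty_synapse_fills_at_presynaptic_rate(self):
        # dP/dt at P=0 equals P_s_max * r (r in spikes/ms)
        assert synapse_derivative(0.0, 50.0) == pytest.approx(0.05)

    def test_fixed_point_matches_root_finding(self):
        r = 30.0
        p_analytic = synapse_fixed_point(r)
        p_root = brentq(lambda p: synapse_derivative(p, r), 0.0, 1.0)
        assert p_analytic == pytest.approx(p_root, abs=1e-12)
        assert synapse_derivative(p_analytic, r) == pytest.approx(0.0, abs=1e-15)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            synapse_derivative(0.5, -1.0)

    def test_convergence_within_one_percent_after_five_tau(self):
        # integrate dP/dt at constant rate from P=0 for 5 tau_s
        r, dt = 30.0, 1.0
        p = 0.0
        for _ in range(int(5 * C.tau_s / dt)):
            # RK4 on the scalar ODE
            k1 = synapse_derivative(p, r)
            k2 = synapse_derivative(p + dt / 2 * k1, r)
            k3 = synapse_derivative(p + dt / 2 * k2, r)
            k4 = synapse_derivative(p + dt * k3, r)
            p += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        fp = synapse_fixed_point(r)
        assert abs(p - fp) / fp < 0.01


class TestReleaseKinetics:
    def test_relaxation_targets(self):
        assert release_derivative(0.3, 0.0) == pytest.approx(-0.3 / C.tau_s_mod)
        assert release_derivative(1.0, C.r_av_max) == pytest.approx(0.0)

    def test_step_response_is_exponential(self):
        # closed form: P(t) = 1 - exp(-t / tau_mod) after a step to r_av_max
        dt, t_end = 0.5, 120.0
        p = 0.0
        for _ in range(int(t_end / dt)):
            k1 = release_derivative(p, C.r_av_max)
            k2 = release_derivative(p + dt / 2 * k1, C.r_av_max)
            k3 = release_derivative(p + dt / 2 * k2, C.r_av_max)
            k4 = release_derivative(p + dt * k3, C.r_av_max)
            p += dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        assert p == pytest.approx(1.0 - np.exp(-t_end / C.tau_s_mod), abs=1e-9)

    def test_out_of_range_rate_rejected(self):
        with pytest.raises(ValueError):
            release_derivative(0.5, C.r_av_max + 1.0)
        with pytest.raises(ValueError):
            release_derivative(0.5, -1.0)


def _zero_weight_engine():
    z = np.zeros((32, 33))
    return CircuitDynamics(z, z.copy(), z.copy(), C)


class TestRK4:
    def test_dt_must_be_positive(self):
        eng = _zero_weight_engine()
        ps = np.full((1, 33), 0.3)
        prel = np.zeros((1, 2))
        with pytest.raises(ValueError):
            eng.rk4_step(ps, prel, np.zeros((1, 2)), 0.0)

    def test_linear_decay_matches_exponential_within_dt5(self):
        # P_rel with zero drive decays linearly: one RK4 step vs exact exp
        eng = _zero_weight_engine()
        ps = np.full((1, 33), 0.5)
        prel = np.array([[1.0, 0.8]])
        dt = 4.0
        _, prel1 = eng.rk4_step(ps, prel, np.zeros((1, 2)), dt)
        exact = prel * np.exp(-dt / C.tau_s_mod)
        # local truncation error bound ~ (dt/tau)^5 / 120
        assert np.max(np.abs(prel1 - exact)) < (dt / C.tau_s_mod) ** 5

    def test_global_error_scales_as_dt_to_the_fourth(self):
        eng = _zero_weight_engine()
        errs = []
        for dt in (8.0, 4.0, 2.0):
            prel = np.array([[1.0, 1.0]])
            ps = np.full((1, 33), 0.5)
            for _ in range(int(80.0 / dt)):
                ps, prel = eng.rk4_step(ps, prel, np.zeros((1, 2)), dt)
            errs.append(abs(prel[0, 0] - np.exp(-80.0 / C.tau_s_mod)))
        # halving dt should shrink the global error ~16x
        assert 8.0 < errs[0] / errs[1] < 32.0
        assert 8.0 < errs[1] / errs[2] < 32.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_probabilities_stay_in_unit_interval(self, seed, mask):
        # random masked weights, random drive: P_s and P_rel remain probabilities
        # weight scale keeps the shunting denominator away from its guard,
        # as any functional (non-degenerate) circuit must
        rng = np.random.default_rng(seed)
        g = np.where(mask.ff_mask, rng.uniform(-0.05, 0.05, (32, 33)), 0.0)
        gc = np.where(mask.mod_mask, rng.uniform(-0.05, 0.05, (32, 33)), 0.0)
        gw = np.where(mask.mod_mask, rng.uniform(-0.05, 0.05, (32, 33)), 0.0)
        eng = CircuitDynamics(g, gc, gw, C)
        ps = rng.uniform(0.0, 1.0, (4, 33))
        prel = rng.uniform(0.0, 1.0, (4, 2))
        for _ in range(100):
            m = rng.uniform(0.0, 1.0, (4, 2))
            ps, prel = eng.rk4_step(ps, prel, m, 2.0)
            assert np.all(ps >= 0.0) and np.all(ps <= 1.0)
            assert np.all(prel >= 0.0) and np.all(prel <= 1.0)


class TestConstants:
    def test_slow_synapse_assumption_enforced(self):
        with pytest.raises(ValueError):
            ModelConstants(tau_s=10.0)  # < 10 * tau_m

    def test_modulatory_synapses_must_be_slower(self):
        with pytest.raises(ValueError):
            ModelConstants(tau_s=50.0, tau_s_mod=40.0)

    def test_p_s_max_fixed_at_one(self):
        with pytest.raises(ValueError):
            ModelConstants(P_s_max=0.9)
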