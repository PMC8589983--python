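"""Unit tests of the transfer functions, currents, derivatives and RK2 step."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adaptconf import (
    ModelParameters,
    NetworkState,
    StimulusSpec,
    confidence_current,
    decision_currents,
    derivatives,
    external_input,
    initial_state,
    phi_confidence,
    phi_decision,
    rk2_step,
)


class TestTransferFunctions:
    @pytest.mark.parametrize(
        "current, expected, tol",
        [
            (0.4, 1 / 0.154, 1e-9),      # removable singularity c_E*I = I_th
            (0.5, 27 / (1 - math.exp(-0.154 * 27)), 1e-9),
            (0.0, 0.0, 1e-4),            # denominator blows up, rate ~ 6.5e-6
        ],
    )
    def test_decision_fi_curve_values(self, current, expected, tol):
        p = ModelParameters()
        assert phi_decision(current, p) == pytest.approx(expected, abs=tol)

    def test_decision_fi_curve_continuous_at_singularity(self):
        p = ModelParameters()
        limit = phi_decision(0.4, p)
        for eps in (1e-9, -1e-9):
            assert phi_decision(0.4 + eps, p) == pytest.approx(limit, rel=1e-6)

    @pytest.mark.parametrize(
        "current, expected",
        [(0.0, 0.5), (0.4, 0.5), (0.5, 27.0)],
    )
    def test_confidence_fi_curve_values(self, current, expected):
        assert phi_confidence(current, ModelParameters()) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(-2.0, 2.0))
    def test_decision_fi_curve_nonnegative_and_monotone(self, current):
        p = ModelParameters()
        r = phi_decision(current, p)
        assert r >= 0.0
        assert phi_decision(current + 1e-3, p) >= r

    @pytest.mark.parametrize("func", [phi_decision, phi_confidence])
    @pytest.mark.parametrize("bad", [np.nan, np.inf, -np.inf])
    def test_nonfinite_current_rejected(self, func, bad):
        with pytest.raises(ValueError):
            func(bad, ModelParameters())


class TestExternalInput:
    def test_table_values(self):
        # an oversized coupling makes the arithmetic easy to verify by hand
        p = ModelParameters(J_ext=0.15)
        assert external_input(StimulusSpec(coherence_pct=0.0), p) == pytest.approx((4.5, 4.5))
        assert external_input(StimulusSpec(coherence_pct=100.0), p) == pytest.approx((9.0, 0.0))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.0, 100.0))
    def test_sum_conserved_across_coherence(self, c):
        p = ModelParameters()
        a, b = external_input(StimulusSpec(coherence_pct=c), p)
        assert a + b == pytest.approx(2 * p.J_ext * p.mu_0, rel=1e-12)

    def test_preferred_pool_sign(self):
        p = ModelParameters()
        a1, b1 = external_input(StimulusSpec(coherence_pct=20, preferred_pool="A"), p)
        a2, b2 = external_input(StimulusSpec(coherence_pct=20, preferred_pool="B"), p)
        assert (a1, b1) == (b2, a2)
        assert a1 > b1

    def test_coherence_above_100_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(coherence_pct=101.0)


class TestCurrents:
    def test_background_only(self):
        p = ModelParameters()
        s = NetworkState()
        ia, ib = decision_currents(s, None, p)
        assert ia == pytest.approx(p.I_0)
        assert ib == pytest.approx(p.I_0)

    def test_recurrent_and_cross_inhibition(self):
        p = ModelParameters()
        s = NetworkState(S_A=1.0, S_B=0.0)
        ia, ib = decision_currents(s, None, p)
        assert ia == pytest.approx(0.3255 + 0.2609)
        assert ib == pytest.approx(0.3255 - 0.0497)

    def test_pool_exchange_symmetry(self):
        p = ModelParameters()
        s = NetworkState(S_A=0.3, S_B=0.7, r_C=5.0, I_noise_A=0.01, I_noise_B=-0.02)
        sw = NetworkState(S_A=0.7, S_B=0.3, r_C=5.0, I_noise_A=-0.02, I_noise_B=0.01)
        stim = StimulusSpec(coherence_pct=10, preferred_pool="A", onset_s=-1.0)
        mirror = StimulusSpec(coherence_pct=10, preferred_pool="B", onset_s=-1.0)
        ia, ib = decision_currents(s, stim, p)
        ja, jb = decision_currents(sw, mirror, p)
        assert ia == pytest.approx(jb) and ib == pytest.approx(ja)

    def test_confidence_current_std_baseline(self):
        p = ModelParameters(variant="std")
        assert confidence_current(NetworkState(), p) == pytest.approx(p.I_0c)

    def test_confidence_current_feedforward_term(self):
        p = ModelParameters(variant="adaptation")
        s = NetworkState(r_A=10.0, r_B=10.0)
        assert confidence_current(s, p) == pytest.approx(0.015 * 20 + 0.2)

    def test_adaptation_with_zero_a_equals_variant_none(self):
        s = NetworkState(S_C=0.4, r_A=7.0, r_B=3.0, a=0.0, I_noise_C=0.01)
        i_adapt = confidence_current(s, ModelParameters(variant="adaptation"))
        i_none = confidence_current(s, ModelParameters(variant="none"))
        assert i_adapt == pytest.approx(i_none)

    def test_std_recurrent_site_depresses_recurrent_term(self):
        s = NetworkState(S_C=0.5, x=0.5)
        p = ModelParameters(variant="std", std_site="recurrent")
        assert confidence_current(s, p) == pytest.approx(0.15 * 0.5 * 0.5 + 0.2)


class TestDerivatives:
    def test_adaptation_fixed_point(self):
        p = ModelParameters(variant="adaptation")
        # da/dt = 0 at a = tau_a (A_1 r_C + A_0); with r_C pinned at 0 that is 0.0075
        s = NetworkState(a=p.tau_a * p.A_0, r_C=0.0)
        d = derivatives(s, None, p)
        assert d["a"] == pytest.approx(0.0, abs=1e-12)

    def test_std_resource_fixed_point(self):
        p = ModelParameters(variant="std", std_site="recurrent")
        r_c = 40.0
        x_inf = 1.0 / (1.0 + p.U_0_eff * p.tau_d * r_c)
        d = derivatives(NetworkState(r_C=r_c, x=x_inf), None, p)
        assert d["x"] == pytest.approx(0.0, abs=1e-12)
        d1 = derivatives(NetworkState(r_C=0.0, x=1.0), None, p)
        assert d1["x"] == pytest.approx(0.0, abs=1e-12)

    def test_nmda_gating_fixed_point_at_zero_rate(self):
        p = ModelParameters()
        d = derivatives(NetworkState(), None, p)
        assert d["S_C"] == pytest.approx(0.0, abs=1e-12)  # r_C = 0, S_C = 0

    def test_rate_relaxation_toward_transfer_function(self):
        p = ModelParameters(variant="none")
        s = NetworkState(r_C=100.0)
        d = derivatives(s, None, p)
        target = phi_confidence(confidence_current(s, p), p)
        # with frozen inputs, dr_C/dt drives r_C toward phi_C
        assert d["r_C"] == pytest.approx((target - 100.0) / p.tau_r)

    def test_literal_rate_equation_mode(self):
        p = ModelParameters(variant="none", rate_eq_mode="literal")
        s = NetworkState(r_C=100.0)
        d = derivatives(s, None, p)
        target = phi_confidence(confidence_current(s, p), p)
        assert d["r_C"] == pytest.approx(-100.0 / p.tau_r + target)


class TestRK2Step:
    def test_fixed_point_preserved(self, fast_params):
        p = dataclasses.replace(fast_params, noise_sigma=0.0, variant="adaptation")
        # self-consistent quiescent fixed point found by relaxation
        s = initial_state(p)
        for _ in range(20000):
            s = rk2_step(s, None, p)
        before = dataclasses.asdict(s)
        after = dataclasses.asdict(rk2_step(s, None, p))
        for key in ("S_A", "S_B", "S_C", "r_C", "a", "x"):
            assert after[key] == pytest.approx(before[key], abs=1e-10)

    def test_gating_clamped_after_step(self):
        p = ModelParameters(dt=5e-3)  # oversized step to force overshoot
        s = NetworkState(S_A=1.0, S_B=0.999, r_C=50.0, x=1e-9)
        out = rk2_step(s, None, p)
        assert 0.0 <= out.S_A <= 1.0 and 0.0 <= out.S_B <= 1.0
        assert 0.0 < out.x <= 1.0 and out.r_C >= 0.0

    def test_pool_relabeling_is_exact_mirror(self, fast_params):
        stim = StimulusSpec(coherence_pct=0.0, preferred_pool="A")
        s = NetworkState(S_A=0.31, S_B=0.12, S_C=0.2, r_C=8.0,
                         I_noise_A=0.004, I_noise_B=-0.009, I_noise_C=0.002, t=0.1)
        sw = NetworkState(S_A=0.12, S_B=0.31, S_C=0.2, r_C=8.0,
                          I_noise_A=-0.009, I_noise_B=0.004, I_noise_C=0.002, t=0.1)
        a = rk2_step(s, stim, fast_params, (0.3, -0.7, 0.1))
        b = rk2_step(sw, stim, fast_params, (-0.7, 0.3, 0.1))
        assert a.S_A == b.S_B and a.S_B == b.S_A          # bit-identical
        assert a.r_A == b.r_B and a.I_noise_A == b.I_noise_B
        assert a.S_C == b.S_C and a.r_C == b.r_C

    def test_gating_bounds_over_many_random_steps(self, rng):
        # batch of random (even inadmissible-extreme) states stepped repeatedly
        p = ModelParameters(dt=5e-4, variant="std")
        n = 500
        s = NetworkState(
            S_A=rng.uniform(0, 1, n), S_B=rng.uniform(0, 1, n),
            S_C=rng.uniform(0, 1, n), r_C=rng.uniform(0, 120, n),
            a=rng.uniform(0, 1, n), x=rng.uniform(0.01, 1, n),
            I_noise_A=rng.normal(0, 0.01, n), I_noise_B=rng.normal(0, 0.01, n),
            I_noise_C=rng.normal(0, 0.01, n),
        )
        stim = StimulusSpec(coherence_pct=51.2)
        for _ in range(25):
            s = rk2_step(s, stim, p, rng.standard_normal((3, n)))
            for g in (s.S_A, s.S_B, s.S_C):
                assert np.all(g >= 0.0) and np.all(g <= 1.0)
            assert np.all(s.x > 0.0) and np.all(s.x <= 1.0)
            assert np.all(s.r_C >= 0.0)

    def test_ou_update_is_distribution_exact(self, rng):
        # variance of the stationary OU process is preserved step to step
        p = ModelParameters(dt=5e-4)
        n = 200_000
        noise = rng.normal(0, p.noise_sigma, n)
        s = NetworkState(I_noise_A=noise, I_noise_B=np.zeros(n), I_noise_C=np.zeros(n))
        out = rk2_step(s, None, p, (rng.standard_normal(n), np.zeros(n), np.zeros(n)))
        assert np.std(out.I_noise_A) == pytest.approx(p.noise_sigma, rel=0.02)
        # and the one-step autocorrelation matches exp(-dt/tau)
        rho = np.corrcoef(noise, out.I_noise_A)[0, 1]
        assert rho == pytest.approx(math.exp(-p.dt / p.noise_tau), abs=0.01)


class TestParameterValidation:
    def test_default_constants_are_standard_operating_point(self):
        p = ModelParameters()
        assert (p.tau_nmda, p.tau_a, p.tau_r, p.tau_d) == (0.1, 0.25, 0.002, 1.0)
        assert (p.theta, p.gamma) == (25.0, 0.641)
        assert (p.J_ii, p.J_ij, p.J_C, p.J_fc, p.J_dc, p.J_a) == (
            0.2609, 0.0497, 0.15, 0.0002, 0.015, 0.001)
        assert (p.c_E, p.I_th, p.g_E, p.I_th_C) == (270.0, 108.0, 0.154, 108.0)
        assert (p.A_1, p.A_0, p.mu_0, p.U_0) == (0.05, 0.03, 30.0, 0.0001)
        assert (p.I_0, p.I_0c, p.dt) == (0.3255, 0.2, 5e-5)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tau_nmda": 0.0},
            {"dt": -1e-5},
            {"U_0": 0.0},
            {"U_0": 1.5},
            {"variant": "spiking"},
            {"rate_eq_mode": "exact"},
            {"std_site": "axon"},
            {"theta": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelParameters(**kwargs)
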