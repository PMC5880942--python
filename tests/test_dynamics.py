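"""Oracle tests for the elementary update steps."""

import numpy as np
import pytest

from dynsyn import NetworkParams
from dynsyn import dynamics as dyn

P = NetworkParams()


class TestExternalCurrent:
    def test_stimulus_and_background_means_without_noise(self):
        p = P.replace(sigma_ext=0.0)
        assert dyn.external_current(True, True, p) == pytest.approx(0.65)
        assert dyn.external_current(True, False, p) == pytest.approx(0.45)
        assert dyn.external_current(False, True, p) == pytest.approx(0.45)

    def test_empirical_mean_matches_mu_within_clt_bound(self):
        rng = np.random.default_rng(0)
        draws = dyn.external_current(True, True, P, rng.standard_normal(100_000))
        se = P.noise_scale / np.sqrt(draws.size)
        assert abs(draws.mean() - P.mu_ext) < 4 * se


class TestStpDecay:
    def test_rest_state_is_fixed_point(self):
        for dt in (0.01, 1.0, 500.0):
            u, x = dyn.stp_decay(0.0, 1.0, dt, P)
            assert u == 0.0 and x == pytest.approx(1.0)

    def test_closed_form_exponential(self):
        u, x = dyn.stp_decay(0.5, 1.0, P.tau_f, P)
        assert u == pytest.approx(0.5 / np.e, rel=1e-12)

    def test_depleted_x_recovers_monotonically_to_one(self):
        xs = [dyn.stp_decay(0.0, 0.0, dt, P)[1] for dt in (10, 100, 1000, 10000)]
        assert np.all(np.diff(xs) > 0) and xs[-1] == pytest.approx(1.0, abs=1e-4)

    def test_corrupted_state_rejected(self):
        with pytest.raises(ValueError):
            dyn.stp_decay(1.2, 0.5, 1.0, P)
        with pytest.raises(ValueError):
            dyn.stp_decay(0.5, -0.1, 1.0, P)


class TestStpOnSpike:
    def test_saturating_case(self):
        assert dyn.stp_on_spike(0.0, 1.0, 1.0) == (1.0, 0.0, 1.0)

    def test_table_increment_arithmetic(self):
        u, x, q = dyn.stp_on_spike(0.0, 1.0, P.U)
        assert u == pytest.approx(0.00525)
        assert q == pytest.approx(0.00525)
        assert x == pytest.approx(1 - 0.00525)

    def test_strict_ode_convention_scales_increment_by_tau(self):
        u, _, _ = dyn.stp_on_spike(0.0, 1.0, P.U,
                                   convention="jump-equals-coefficient-over-tau",
                                   tau_f=P.tau_f)
        assert u == pytest.approx(P.U / P.tau_f)


class TestAdaptation:
    def test_pure_decay_time_constant(self):
        p = P.replace(dt=0.01)
        i = 2.0
        n = round(p.tau_a / p.dt)
        for _ in range(n):
            i = dyn.adaptation_step(i, p.E_L, False, p.dt, p)
        assert i == pytest.approx(2.0 / np.e, rel=2e-4)  # Euler O(dt) bias

    def test_subthreshold_fixed_point(self):
        # clamped V - E_L = 10 mV -> steady state A_p * 10 = 1.0 uA
        i = 0.0
        for _ in range(100_000):
            i = dyn.adaptation_step(i, P.E_L + 10.0, False, 0.1, P)
        assert i == pytest.approx(P.A_p * 10.0, rel=1e-9)

    def test_spike_jump_equals_A_s(self):
        before = dyn.adaptation_step(0.5, P.E_L, False, 0.1, P)
        after = dyn.adaptation_step(0.5, P.E_L, True, 0.1, P)
        assert after - before == pytest.approx(P.A_s)


class TestRecurrentCurrent:
    def test_decay_toward_zero(self):
        i = dyn.recurrent_current_step(3.0, 0.0, P.tau_s, P)
        assert i == pytest.approx(3.0 / np.e, rel=1e-12)

    def test_single_spike_jump_is_weighted_transmission(self):
        _, _, q = dyn.stp_on_spike(0.02, 0.9, P.U)
        i = dyn.recurrent_current_step(0.0, P.J_EE * q, P.dt, P)
        assert i == pytest.approx(P.J_EE * q)

    def test_simultaneous_spikes_superpose_linearly(self):
        a = dyn.recurrent_current_step(1.0, 0.3, 0.1, P)
        b = dyn.recurrent_current_step(1.0, 0.5, 0.1, P)
        ab = dyn.recurrent_current_step(1.0, 0.8, 0.1, P)
        base = dyn.recurrent_current_step(1.0, 0.0, 0.1, P)
        assert ab - base == pytest.approx((a - base) + (b - base))


class TestMembrane:
    def test_rest_is_fixed_point(self):
        v, spiked = dyn.membrane_step(P.E_L, 0.0, 0.0, 0.1, P)
        assert v == P.E_L and not spiked

    def test_euler_matches_closed_form_with_first_order_convergence(self):
        I = 5.0  # subthreshold: R_m * I = 5 mV < 10 mV
        t_end = 60.0
        errs = []
        for dt in (0.5, 0.25):
            v = P.E_L
            for _ in range(round(t_end / dt)):
                v, _ = dyn.membrane_step(v, I, 0.0, dt, P)
            exact = P.E_L + P.R_m * I * (1 - np.exp(-t_end / P.tau_m))
            errs.append(abs(v - exact))
        assert 1.6 < errs[0] / errs[1] < 2.4  # O(dt) halving

    @pytest.mark.parametrize("current,should_spike", [(10.5, True), (9.5, False)])
    def test_rheobase_threshold_condition(self, current, should_spike):
        v, fired = P.E_L, False
        for _ in range(100_000):
            v, s = dyn.membrane_step(v, current, 0.0, 0.1, P)
            fired = fired or s
        assert fired == should_spike

    def test_nonfinite_voltage_raises(self):
        with pytest.raises(FloatingPointError):
            dyn.membrane_step(np.nan, 0.0, 0.0, 0.1, P)


class TestReadout:
    def test_relaxes_to_rest_without_spikes(self):
        v, ie, ii = P.E_L - 5.0, 0.0, 0.0
        for _ in range(10_000):
            v, ie, ii, _ = dyn.readout_step(v, ie, ii, 0, 0, 0.1, P)
        assert v == pytest.approx(P.E_L, abs=1e-9)

    def test_balanced_poisson_inputs_give_zero_mean_drive(self):
        # rate_I = 2 rate_E per neuron with N_E = 4 N_I and J_IO = 2 J_EO
        # -> J_EO * N_E * r_E == J_IO * N_I * r_I exactly.
        r_e, n_e, n_i = 0.007, P.N_E, P.N_I
        r_i = 2 * r_e
        assert P.J_EO * n_e * r_e == pytest.approx(P.J_IO * n_i * r_i)
        rng = np.random.default_rng(3)
        dt = 0.1
        n_steps = 50_000
        v, ie, ii = P.E_L, 0.0, 0.0
        drives = np.empty(n_steps)
        for k in range(n_steps):
            e = rng.poisson(n_e * r_e * dt)
            i = rng.poisson(n_i * r_i * dt)
            v, ie, ii, _ = dyn.readout_step(v, ie, ii, e, i, dt, P)
            drives[k] = P.R_m * (P.J_EO * ie - P.J_IO * ii)
        n_eff = n_steps * dt / P.tau_s  # decorrelated samples
        se = drives.std() / np.sqrt(n_eff)
        assert abs(drives.mean()) < 4 * se

    def test_synchronous_volley_peak_matches_double_exponential(self):
        # m spikes at t=0: filtered drive A e^{-t/tau_s} with A = R J_EO m;
        # V - E_L = A tau_s/(tau_o - tau_s) (e^{-t/tau_o} - e^{-t/tau_s}).
        m = 3
        p = P.replace(V_th_E=0.0)  # keep subthreshold
        dt = 0.002
        v, ie, ii = p.E_L, 0.0, 0.0
        v, ie, ii, _ = dyn.readout_step(v, ie, ii, m, 0, dt, p)
        peak = -np.inf
        for _ in range(round(60.0 / dt)):
            v, ie, ii, _ = dyn.readout_step(v, ie, ii, 0, 0, dt, p)
            peak = max(peak, v - p.E_L)
        A = p.R_m * p.J_EO * m
        t = np.linspace(0, 60, 60_001)
        exact = A * p.tau_s / (p.tau_o - p.tau_s) * (np.exp(-t / p.tau_o) - np.exp(-t / p.tau_s))
        assert peak == pytest.approx(exact.max(), rel=5e-3)
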