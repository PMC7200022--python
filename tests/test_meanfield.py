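"""Cascade mean-field model: fixed points, invariants, convergence."""

import numpy as np
import pytest

import adexfield as af
from conftest import constant_rate_table


def _uncoupled_net(mu_E, mu_I=0.0, sigma=1.5):
    return af.NetworkParams(K_E=0, K_I=0, mu_ext_E=mu_E, mu_ext_I=mu_I,
                            sigma_ext=sigma)


class TestFixedPoints:
    def test_uncoupled_rate_is_static_nonlinearity(self, eif, table):
        """With all coupling removed, mu relaxes to the external drive and
        the asymptotic rate equals Phi(mu_ext, sigma_ext)."""
        net = _uncoupled_net(0.8, 0.3)
        tr = af.simulate_meanfield(eif, net, table, duration=2000.0, dt=0.05)
        assert tr.mu_E[-1] == pytest.approx(0.8, abs=1e-6)
        assert tr.mu_I[-1] == pytest.approx(0.3, abs=1e-6)
        expected = af.stationary_rate_and_voltage(eif, 0.8, 1.5)[0] * 1e3
        assert tr.r_E[-1] == pytest.approx(expected, rel=0.02)

    def test_sigma_reduces_to_external_noise_without_coupling(self, eif, table):
        tr = af.simulate_meanfield(eif, _uncoupled_net(0.5), table,
                                   duration=500.0, dt=0.05)
        assert np.allclose(tr.sigma_E, 1.5)
        assert np.allclose(tr.sigma_I, 1.5)

    def test_synaptic_mean_converges_to_closed_form(self, eif):
        """At a pinned presynaptic rate r, s_bar -> tau_s r_eff/(1+tau_s r_eff)
        with r_eff = (c/|J|) K r."""
        rate_kHz = 0.02
        tables = constant_rate_table(rate_kHz)
        net = af.NetworkParams(mu_ext_E=1.0, mu_ext_I=1.0)
        tr = af.simulate_meanfield(eif, net, tables, duration=3000.0, dt=0.05)
        # with every rate pinned, mu_syn settles to J_EE s*_EE + J_EI s*_EI
        reff_EE = net.c_EE / abs(net.J_EE) * net.K_E * rate_kHz
        reff_EI = net.c_EI / abs(net.J_EI) * net.K_I * rate_kHz
        s_EE = af.synaptic_steady_state(reff_EE, net.tau_s_E)
        s_EI = af.synaptic_steady_state(reff_EI, net.tau_s_I)
        expected = net.J_EE * s_EE + net.J_EI * s_EI + net.mu_ext_E
        assert tr.mu_E[-1] == pytest.approx(expected, rel=1e-3)

    def test_adaptation_spike_triggered_steady_state(self, adex):
        """With a = 0 and b > 0 at pinned rate r, I_A -> tau_A b r."""
        from dataclasses import replace

        neuron = replace(adex, a=0.0)
        rate_kHz = 0.01
        tables = constant_rate_table(rate_kHz)
        net = af.NetworkParams(K_E=0, K_I=0, mu_ext_E=1.0, mu_ext_I=1.0)
        tr = af.simulate_meanfield(neuron, net, tables, duration=3000.0,
                                   dt=0.05)
        assert tr.I_A[-1] == pytest.approx(neuron.tau_A * neuron.b * rate_kHz,
                                           rel=1e-3)

    def test_adaptation_subthreshold_steady_state(self, adex):
        """With b = 0, I_A -> a (V_E - E_A) at the tabulated mean voltage."""
        from dataclasses import replace

        neuron = replace(adex, b=0.0)
        vmean = -58.0
        tables = constant_rate_table(0.005, vmean=vmean)
        net = af.NetworkParams(K_E=0, K_I=0, mu_ext_E=1.0, mu_ext_I=1.0)
        tr = af.simulate_meanfield(neuron, net, tables, duration=5000.0,
                                   dt=0.05)
        assert tr.I_A[-1] == pytest.approx(neuron.a * (vmean - neuron.E_A),
                                           rel=1e-3)


class TestOperatingPoints:
    def test_A2_oscillates_near_22Hz(self, eif, table):
        muE, muI = af.operating_point_drive("A2", "meanfield")
        net = af.NetworkParams(mu_ext_E=muE, mu_ext_I=muI)
        tr = af.simulate_meanfield(eif, net, table, duration=6000.0, dt=0.05)
        seg = tr.after(1000.0)
        spec = af.welch_spectrum(seg.r_E, tr.dt, 1000.0)
        assert spec.dominant_frequency == pytest.approx(22.0, abs=2.0)
        assert spec.dominant_power > 1.0

    def test_A1_is_a_constant_low_rate_state(self, eif, table):
        muE, muI = af.operating_point_drive("A1", "meanfield")
        net = af.NetworkParams(mu_ext_E=muE, mu_ext_I=muI)
        tr = af.simulate_meanfield(eif, net, table, duration=4000.0, dt=0.05)
        seg = tr.after(2000.0)
        assert seg.r_E.mean() < 5.0
        assert seg.r_E.std() < 0.5

    def test_B3_slow_oscillation_in_range(self, adex, table):
        muE, muI = af.operating_point_drive("B3", "meanfield")
        net = af.NetworkParams(mu_ext_E=muE, mu_ext_I=muI)
        tr = af.simulate_meanfield(adex, net, table, duration=10000.0, dt=0.01)
        seg = tr.after(2000.0)
        spec = af.welch_spectrum(seg.r_E, tr.dt, 2000.0)
        assert 0.5 <= spec.dominant_frequency <= 5.0

    def test_halving_dt_shifts_A2_frequency_below_2_percent(self, eif, table):
        muE, muI = af.operating_point_drive("A2", "meanfield")
        net = af.NetworkParams(mu_ext_E=muE, mu_ext_I=muI)
        doms = []
        for dt in (0.05, 0.025):
            tr = af.simulate_meanfield(eif, net, table, duration=6000.0, dt=dt)
            seg = tr.after(1000.0)
            # zero-padded periodogram for sub-bin frequency resolution
            x = seg.r_E - seg.r_E.mean()
            n = len(x)
            freqs = np.fft.rfftfreq(4 * n, d=dt * 1e-3)
            amp = np.abs(np.fft.rfft(x, 4 * n))
            doms.append(freqs[np.argmax(amp)])
        assert abs(doms[1] - doms[0]) / doms[0] < 0.02


class TestStepwiseReference:
    def test_python_stepper_matches_compiled_integrator(self, eif, table):
        """Integrating the explicit single-step update reproduces the
        compiled trace (dual-route consistency of the cascade equations)."""
        muE, muI = af.operating_point_drive("A2", "meanfield")
        net = af.NetworkParams(mu_ext_E=muE, mu_ext_I=muI)
        dt, n = 0.05, 400
        tr = af.simulate_meanfield(eif, net, table, duration=n * dt, dt=dt)
        state = af.initial_state(eif, net, table, dt)
        hist_len = state.rate_history.shape[1]
        rates = []
        for t in range(n):
            af.step_meanfield(state, table, eif, net, 0.0, dt)
            rates.append(state.rate_history[0, t % hist_len] * 1e3)
        assert np.allclose(rates, tr.r_E, rtol=1e-10, atol=1e-10)


class TestInvariants:
    def test_rates_nonnegative_and_finite_across_drives(self, eif, table):
        for muE, muI in [(0.0, 0.0), (2.0, 0.5), (4.0, 2.0), (-1.0, 1.0)]:
            net = af.NetworkParams(mu_ext_E=muE, mu_ext_I=muI)
            tr = af.simulate_meanfield(eif, net, table, duration=1000.0,
                                       dt=0.05)
            assert np.all(np.isfinite(tr.r_E)) and np.all(tr.r_E >= 0)
            assert np.all(np.isfinite(tr.r_I)) and np.all(tr.r_I >= 0)
            assert np.all(tr.sigma_E >= net.sigma_ext - 1e-9)

    def test_duration_must_exceed_delay(self, eif, table):
        net = af.NetworkParams(mu_ext_E=1.0, mu_ext_I=1.0)
        with pytest.raises(ValueError):
            af.simulate_meanfield(eif, net, table, duration=2.0, dt=0.05)

    def test_stimulus_shorter_than_window_rejected(self, eif, table):
        net = af.NetworkParams(mu_ext_E=1.0, mu_ext_I=1.0)
        wave = af.dc_step(10.0, 0.0, 50.0).sample(100.0, 0.05)
        with pytest.raises(ValueError):
            af.simulate_meanfield(eif, net, table, stimulus=wave,
                                  duration=500.0, dt=0.05)
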