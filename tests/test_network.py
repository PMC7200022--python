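"""Spiking-network simulator: connectivity, single-neuron dynamics, rates."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

import adexfield as af


class TestConnectivity:
    def test_constant_row_sum(self):
        G = af.build_connectivity(5, 4, 2, seed=1)
        assert G.shape == (4, 5)
        assert np.all(G.sum(axis=1) == 2)

    def test_zero_in_degree_gives_empty_matrix(self):
        G = af.build_connectivity(100, 10, 0)
        assert G.sum() == 0

    def test_full_recurrent_without_self_is_off_diagonal_ones(self):
        G = af.build_connectivity(4, 4, 3, self_connections=False, seed=7)
        assert np.all(G + np.eye(4, dtype=G.dtype) == 1)

    def test_reproducible_under_seed(self):
        a = af.build_connectivity(50, 40, 10, seed=3)
        b = af.build_connectivity(50, 40, 10, seed=3)
        c = af.build_connectivity(50, 40, 10, seed=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_in_degree_too_large_rejected(self):
        with pytest.raises(ValueError):
            af.build_connectivity(5, 5, 5, self_connections=False)


def _uncoupled(mu_E, sigma=0.0, N=1):
    return af.NetworkParams(N_E=N, N_I=1, K_E=0, K_I=0,
                            mu_ext_E=mu_E, mu_ext_I=-5.0, sigma_ext=sigma)


class TestSingleNeuron:
    def test_tonic_isi_matches_adaptive_ode_oracle(self, eif):
        """Deterministic EIF at C*mu = 0.5 nA: the network integrator's
        inter-spike interval must match an adaptive-step scalar integration
        of the same ODE (with reset and refractoriness) within 1%."""
        mu = 0.5e3 / eif.C  # 0.5 nA -> 2.5 mV/ms
        res = af.simulate_network(eif, _uncoupled(mu), duration=1000.0,
                                  dt=0.01, seed=1)
        isis = np.diff(res.raster_E.spike_trains()[0])
        assert len(isis) > 10
        assert isis.std() < 1e-9  # perfectly periodic without noise

        def f(t, y):
            V = min(y[0], eif.V_s)
            return [(eif.E_L - V) / eif.tau_m
                    + (eif.Delta_T / eif.tau_m)
                    * np.exp((V - eif.V_T) / eif.Delta_T) + mu]

        def hit(t, y):
            return y[0] - eif.V_s
        hit.terminal = True
        hit.direction = 1
        sol = solve_ivp(f, [0.0, 1000.0], [eif.V_r], events=hit,
                        rtol=1e-10, atol=1e-10, max_step=0.5)
        isi_oracle = sol.t_events[0][0] + eif.T_ref
        assert isis.mean() == pytest.approx(isi_oracle, rel=0.01)

    def test_subthreshold_drive_never_spikes(self, eif):
        # C*mu = -1 nA, no noise: resting equilibrium far below threshold
        res = af.simulate_network(eif, _uncoupled(-5.0), duration=1000.0,
                                  dt=0.1, seed=2)
        assert len(res.raster_E.times) == 0
        assert np.all(res.rate_E.rate == 0.0)

    def test_refractory_period_respected(self, eif):
        res = af.simulate_network(eif, _uncoupled(5.0, sigma=1.5, N=50),
                                  duration=500.0, dt=0.1, seed=3)
        for ts in res.raster_E.spike_trains().values():
            if len(ts) > 1:
                assert np.diff(ts).min() >= eif.T_ref - 1e-9

    def test_voltage_relaxes_to_ionic_root(self, adex):
        """With coupling and noise removed, the mean adaptation current
        settles to the value at the subthreshold fixed point of the coupled
        (V, I_A) system, verified against a scalar root-finder."""
        mu = -1.0
        res = af.simulate_network(adex, _uncoupled(mu), duration=3000.0,
                                  dt=0.1, seed=4)

        def ionic(V):
            # stationary I_A = a (V - E_A); total drift must vanish
            IA = adex.a * (V - adex.E_A)
            return ((adex.E_L - V) / adex.tau_m
                    + (adex.Delta_T / adex.tau_m)
                    * np.exp((V - adex.V_T) / adex.Delta_T)
                    - IA / adex.C + mu)

        V_star = brentq(ionic, -120.0, adex.V_T)
        IA_star = adex.a * (V_star - adex.E_A)
        assert res.adaptation_mean[-1] == pytest.approx(IA_star, abs=1.0)


class TestNetworkProperties:
    def test_identical_seeds_bit_identical(self, eif):
        net = af.NetworkParams(N_E=200, N_I=200, K_E=40, K_I=10,
                               mu_ext_E=1.2, mu_ext_I=0.8)
        a = af.simulate_network(eif, net, duration=500.0, dt=0.1, seed=9)
        b = af.simulate_network(eif, net, duration=500.0, dt=0.1, seed=9)
        assert np.array_equal(a.rate_E.rate, b.rate_E.rate)
        assert np.array_equal(a.raster_E.times, b.raster_E.times)

    def test_different_seed_differs(self, eif):
        net = af.NetworkParams(N_E=100, N_I=100, K_E=20, K_I=5,
                               mu_ext_E=1.2, mu_ext_I=0.8)
        a = af.simulate_network(eif, net, duration=300.0, dt=0.1, seed=1)
        b = af.simulate_network(eif, net, duration=300.0, dt=0.1, seed=2)
        assert not np.array_equal(a.rate_E.rate, b.rate_E.rate)

    def test_delay_below_dt_rejected(self, eif):
        net = af.NetworkParams(N_E=10, N_I=10, K_E=2, K_I=2, d_E=0.05)
        with pytest.raises(ValueError):
            af.simulate_network(eif, net, duration=10.0, dt=0.1)


class TestPopulationRate:
    def test_single_bin_formula(self):
        # 50 spikes among N=1000 within one 1-ms bin -> 50 Hz
        raster = af.SpikeRaster(np.arange(50), np.full(50, 0.5),
                                n_neurons=1000, duration=2.0)
        tr = af.population_rate(raster, dt=1.0)
        assert tr.rate[0] == pytest.approx(50.0)
        assert tr.rate[1] == 0.0

    def test_empty_raster_is_zero(self):
        raster = af.SpikeRaster(np.array([], int), np.array([]), 10, 100.0)
        assert np.all(af.population_rate(raster, 1.0).rate == 0.0)

    def test_no_neurons_rejected(self):
        raster = af.SpikeRaster(np.array([], int), np.array([]), 0, 100.0)
        with pytest.raises(ValueError):
            af.population_rate(raster, 1.0)

    def test_poisson_population_recovers_rate(self):
        """10^3 independent 5 Hz Poisson trains over 10 s average to 5 Hz
        within 3 standard errors of the total count."""
        rng = np.random.default_rng(11)
        N, T, rate = 1000, 10000.0, 5.0
        n_sp = rng.poisson(rate * T * 1e-3 * N)
        times = np.sort(rng.uniform(0, T, n_sp))
        ids = rng.integers(0, N, n_sp)
        tr = af.population_rate(af.SpikeRaster(ids, times, N, T), dt=1.0)
        se = np.sqrt(rate * T * 1e-3 * N) / (N * T * 1e-3)
        assert tr.rate.mean() == pytest.approx(rate, abs=3 * se)

    def test_rate_trace_matches_simulator_counts(self, eif):
        # spikes are stamped at the end of their step, so the rebuilt trace
        # lags the online one by exactly one bin
        res = af.simulate_network(eif, _uncoupled(2.0, sigma=1.0, N=100),
                                  duration=200.0, dt=0.1, seed=5)
        rebuilt = af.population_rate(res.raster_E, 0.1)
        assert np.allclose(rebuilt.rate[1:-1], res.rate_E.rate[:-2])


class TestRasterIO:
    def test_text_and_binary_round_trip(self, eif, tmp_path):
        res = af.simulate_network(eif, _uncoupled(2.0, sigma=1.0, N=20),
                                  duration=200.0, dt=0.1, seed=8)
        npz = tmp_path / "raster.npz"
        res.raster_E.save(npz, dt=0.1, seed=8)
        loaded = af.SpikeRaster.load(npz)
        assert np.array_equal(loaded.times, res.raster_E.times)
        assert np.array_equal(loaded.neuron_ids, res.raster_E.neuron_ids)
        assert loaded.n_neurons == 20

        txt = tmp_path / "raster.txt"
        res.raster_E.to_text(txt)
        ids, times = np.loadtxt(txt, unpack=True)
        assert np.all(np.diff(times) >= 0)
        assert len(ids) == len(res.raster_E.times)
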