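"""Spiking simulator of the delay-coupled E-I network of AdEx neurons.

Each population is a homogeneous pool of AdEx neurons coupled through
current-based saturating synapses: the gating variable ``s`` of each
projection decays exponentially and is incremented by ``(c/|J|)(1 - s)``
per arriving spike, so it stays in [0, 1] and the synaptic current is
``C * J * s``.  Connectivity is a random binary matrix with a constant
in-degree per projection, regenerated from the seed for every simulation.
Integration is stochastic Heun (the same Gaussian increment enters the
predictor and the corrector); spikes are detected after the corrector step,
the voltage reset to ``V_r`` and clamped for the refractory period while
adaptation and synapses keep evolving.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from numba import njit

from .params import NetworkParams, NeuronParams
from .stimuli import Stimulus, StimulusWaveform, ZeroStimulus

__all__ = ["SpikeRaster", "RateTrace", "build_connectivity",
           "simulate_network", "population_rate", "NetworkResult"]


@dataclass
class SpikeRaster:
    """Spike times per neuron of one population."""

    neuron_ids: np.ndarray   # int, parallel to times
    times: np.ndarray        # ms, sorted
    n_neurons: int
    duration: float
    population: str = "E"

    def spike_trains(self) -> Dict[int, np.ndarray]:
        order = np.argsort(self.neuron_ids, kind="stable")
        ids = self.neuron_ids[order]
        ts = self.times[order]
        bounds = np.searchsorted(ids, np.arange(self.n_neurons + 1))
        return {i: np.sort(ts[bounds[i]:bounds[i + 1]])
                for i in range(self.n_neurons) if bounds[i] < bounds[i + 1]}

    def to_text(self, path) -> None:
        """Two-column plain text (neuron_id, time_ms), sorted by time."""
        order = np.argsort(self.times, kind="stable")
        np.savetxt(path, np.column_stack([self.neuron_ids[order],
                                          self.times[order]]),
                   fmt=("%d", "%.6f"), header="neuron_id time_ms")

    def save(self, path, dt: float | None = None, seed: int | None = None,
             params_hash: str = "") -> None:
        """Compact binary container (.npz) with run metadata."""
        import json

        meta = json.dumps({"n_neurons": self.n_neurons,
                           "duration": self.duration,
                           "population": self.population,
                           "dt": dt, "seed": seed,
                           "params_hash": params_hash})
        np.savez_compressed(path, neuron_ids=self.neuron_ids,
                            times=self.times, meta=np.array(meta))

    @classmethod
    def load(cls, path) -> "SpikeRaster":
        import json

        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            return cls(data["neuron_ids"], data["times"],
                       meta["n_neurons"], meta["duration"],
                       meta["population"])


@dataclass
class RateTrace:
    """Population rate on a uniform grid, in Hz."""

    time: np.ndarray
    rate: np.ndarray
    population: str = "E"

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def after(self, t_ms: float) -> "RateTrace":
        i = int(np.searchsorted(self.time, t_ms))
        return RateTrace(self.time[i:], self.rate[i:], self.population)


def build_connectivity(n_pre: int, n_post: int, in_degree: int,
                       self_connections: bool = False,
                       seed: int = 0) -> np.ndarray:
    """Random binary adjacency with a constant row sum.

    Row i lists the afferents of post-synaptic neuron i: each row has
    exactly ``in_degree`` ones in random columns.  For recurrent projections
    (``n_pre == n_post``) self-connections are excluded unless requested.
    """
    idx = _sample_in_edges(n_pre, n_post, in_degree, self_connections, seed)
    G = np.zeros((n_post, n_pre), dtype=np.uint8)
    rows = np.repeat(np.arange(n_post), in_degree)
    G[rows, idx.ravel()] = 1
    return G


def _sample_in_edges(n_pre: int, n_post: int, in_degree: int,
                     self_connections: bool, seed: int) -> np.ndarray:
    """(n_post, in_degree) array of presynaptic indices, no repeats per row."""
    recurrent = n_pre == n_post and not self_connections
    avail = n_pre - 1 if recurrent else n_pre
    if in_degree < 0 or in_degree > avail:
        raise ValueError(
            f"in_degree {in_degree} too large for {n_pre} presynaptic neurons"
            + (" (self-connections excluded)" if recurrent else ""))
    rng = np.random.default_rng(seed)
    idx = np.empty((n_post, in_degree), dtype=np.int64)
    for i in range(n_post):
        row = rng.choice(avail, size=in_degree, replace=False)
        if recurrent:
            row = row + (row >= i)
        idx[i] = row
    return idx


def _outgoing_csr(in_edges: np.ndarray, n_pre: int) -> Tuple[np.ndarray, np.ndarray]:
    """Convert per-post afferent lists to an outgoing CSR (indptr, targets)."""
    n_post, k = in_edges.shape
    pre = in_edges.ravel()
    post = np.repeat(np.arange(n_post), k)
    order = np.argsort(pre, kind="stable")
    targets = post[order].astype(np.int64)
    counts = np.bincount(pre, minlength=n_pre)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    return indptr, targets


@njit(cache=True, fastmath=True)
def _run_network(n_steps, dt, N_E, N_I,
                 C, g_L, E_L, Delta_T, V_T, V_s, V_r, ref_steps,
                 a, b, E_A, tau_A,
                 J, m, tau_s, dE_steps, dI_steps,
                 mu_ext_E, mu_ext_I, sigma_ext,
                 ptr_EE, tg_EE, ptr_IE, tg_IE, ptr_EI, tg_EI, ptr_II, tg_II,
                 seed, record_spikes, spike_cap):
    np.random.seed(seed)
    tau_m = C / g_L
    sq = sigma_ext * np.sqrt(dt)

    V_E = np.random.uniform(V_r, V_T, N_E)
    V_I = np.random.uniform(V_r, V_T, N_I)
    IA = np.zeros(N_E)
    s_EE = np.zeros(N_E)
    s_EI = np.zeros(N_E)
    s_IE = np.zeros(N_I)
    s_II = np.zeros(N_I)
    ref_E = np.zeros(N_E, dtype=np.int64)
    ref_I = np.zeros(N_I, dtype=np.int64)

    # ring length d+1: the write slot (t+d) % L never collides with the
    # read slot t % L, so spikes scattered mid-step cannot be delivered early
    L_E = dE_steps + 1
    L_I = dI_steps + 1
    buf_EE = np.zeros((L_E, N_E))
    buf_EI = np.zeros((L_E, N_E))
    buf_IE = np.zeros((L_I, N_I))
    buf_II = np.zeros((L_I, N_I))

    rate_E = np.zeros(n_steps)
    rate_I = np.zeros(n_steps)
    IA_mean = np.zeros(n_steps)
    sp_id = np.empty(spike_cap, dtype=np.int64)
    sp_t = np.empty(spike_cap, dtype=np.float64)
    sp_pop = np.empty(spike_cap, dtype=np.int64)
    n_sp = 0
    truncated = False

    # single-spike increment factors and exp decay per projection
    m_EE, m_IE, m_EI, m_II = m[0], m[1], m[2], m[3]
    ts_EE, ts_IE, ts_EI, ts_II = tau_s[0], tau_s[1], tau_s[2], tau_s[3]

    # Heun decay factors for the linear synaptic decay
    dec_EE = 1.0 - dt / ts_EE + 0.5 * (dt / ts_EE) ** 2
    dec_EI = 1.0 - dt / ts_EI + 0.5 * (dt / ts_EI) ** 2
    dec_IE = 1.0 - dt / ts_IE + 0.5 * (dt / ts_IE) ** 2
    dec_II = 1.0 - dt / ts_II + 0.5 * (dt / ts_II) ** 2
    inv_tau_m = 1.0 / tau_m
    inv_DT = 1.0 / Delta_T

    for t in range(n_steps):
        slot_E = t % L_E
        slot_I = t % L_I
        wslot_E = (t + dE_steps) % L_E
        wslot_I = (t + dI_steps) % L_I

        # --- E population: arrivals, stochastic Heun for (V, IA), decay -----
        nspE = 0
        IA_sum = 0.0
        for i in range(N_E):
            A = buf_EE[slot_E, i]
            if A > 0.0:
                if A == 1.0:
                    s_EE[i] += m_EE * (1.0 - s_EE[i])
                else:
                    s_EE[i] = 1.0 - (1.0 - s_EE[i]) * (1.0 - m_EE) ** A
                buf_EE[slot_E, i] = 0.0
            A = buf_EI[slot_E, i]
            if A > 0.0:
                if A == 1.0:
                    s_EI[i] += m_EI * (1.0 - s_EI[i])
                else:
                    s_EI[i] = 1.0 - (1.0 - s_EI[i]) * (1.0 - m_EI) ** A
                buf_EI[slot_E, i] = 0.0
            drive = mu_ext_E[t] + J[0] * s_EE[i] + J[2] * s_EI[i]
            if ref_E[i] > 0:
                ref_E[i] -= 1
                V_E[i] = V_r
                IA[i] += dt * (a * (V_r - E_A) - IA[i]) / tau_A
            else:
                xi = sq * np.random.standard_normal()
                ex0 = (V_E[i] - V_T) * inv_DT
                if ex0 > 15.0:
                    ex0 = 15.0
                f0 = ((E_L - V_E[i]) + Delta_T * np.exp(ex0)) * inv_tau_m \
                    - IA[i] / C + drive
                g0 = (a * (V_E[i] - E_A) - IA[i]) / tau_A
                Vp = V_E[i] + dt * f0 + xi
                IAp = IA[i] + dt * g0
                ex1 = (Vp - V_T) * inv_DT
                if ex1 > 15.0:
                    ex1 = 15.0
                f1 = ((E_L - Vp) + Delta_T * np.exp(ex1)) * inv_tau_m \
                    - IAp / C + drive
                g1 = (a * (Vp - E_A) - IAp) / tau_A
                V_E[i] += 0.5 * dt * (f0 + f1) + xi
                IA[i] += 0.5 * dt * (g0 + g1)
                if V_E[i] >= V_s:
                    V_E[i] = V_r
                    ref_E[i] = ref_steps
                    IA[i] += b
                    nspE += 1
                    # scatter to targets with the appropriate delay
                    for q in range(ptr_EE[i], ptr_EE[i + 1]):
                        buf_EE[wslot_E, tg_EE[q]] += 1.0
                    for q in range(ptr_IE[i], ptr_IE[i + 1]):
                        buf_IE[wslot_I, tg_IE[q]] += 1.0
                    if record_spikes:
                        if n_sp < spike_cap:
                            sp_id[n_sp] = i
                            sp_t[n_sp] = (t + 1) * dt
                            sp_pop[n_sp] = 0
                            n_sp += 1
                        else:
                            truncated = True
            s_EE[i] *= dec_EE
            s_EI[i] *= dec_EI
            IA_sum += IA[i]

        # --- I population ---------------------------------------------------
        nspI = 0
        for i in range(N_I):
            A = buf_IE[slot_I, i]
            if A > 0.0:
                if A == 1.0:
                    s_IE[i] += m_IE * (1.0 - s_IE[i])
                else:
                    s_IE[i] = 1.0 - (1.0 - s_IE[i]) * (1.0 - m_IE) ** A
                buf_IE[slot_I, i] = 0.0
            A = buf_II[slot_I, i]
            if A > 0.0:
                if A == 1.0:
                    s_II[i] += m_II * (1.0 - s_II[i])
                else:
                    s_II[i] = 1.0 - (1.0 - s_II[i]) * (1.0 - m_II) ** A
                buf_II[slot_I, i] = 0.0
            drive = mu_ext_I[t] + J[1] * s_IE[i] + J[3] * s_II[i]
            if ref_I[i] > 0:
                ref_I[i] -= 1
                V_I[i] = V_r
            else:
                xi = sq * np.random.standard_normal()
                ex0 = (V_I[i] - V_T) * inv_DT
                if ex0 > 15.0:
                    ex0 = 15.0
                f0 = ((E_L - V_I[i]) + Delta_T * np.exp(ex0)) * inv_tau_m \
                    + drive
                Vp = V_I[i] + dt * f0 + xi
                ex1 = (Vp - V_T) * inv_DT
                if ex1 > 15.0:
                    ex1 = 15.0
                f1 = ((E_L - Vp) + Delta_T * np.exp(ex1)) * inv_tau_m + drive
                V_I[i] += 0.5 * dt * (f0 + f1) + xi
                if V_I[i] >= V_s:
                    V_I[i] = V_r
                    ref_I[i] = ref_steps
                    nspI += 1
                    for q in range(ptr_EI[i], ptr_EI[i + 1]):
                        buf_EI[wslot_E, tg_EI[q]] += 1.0
                    for q in range(ptr_II[i], ptr_II[i + 1]):
                        buf_II[wslot_I, tg_II[q]] += 1.0
                    if record_spikes:
                        if n_sp < spike_cap:
                            sp_id[n_sp] = i
                            sp_t[n_sp] = (t + 1) * dt
                            sp_pop[n_sp] = 1
                            n_sp += 1
                        else:
                            truncated = True
            s_IE[i] *= dec_IE
            s_II[i] *= dec_II

        rate_E[t] = nspE / (N_E * dt * 1e-3)
        rate_I[t] = nspI / (N_I * dt * 1e-3)
        IA_mean[t] = IA_sum / N_E
        # amortized divergence check: a NaN poisons the sums immediately
        if (t & 255) == 0:
            chk = 0.0
            for i in range(N_E):
                chk += V_E[i]
            for i in range(N_I):
                chk += V_I[i]
            if not np.isfinite(chk):
                raise FloatingPointError("non-finite membrane voltage")

    return (rate_E, rate_I, IA_mean, sp_id[:n_sp], sp_t[:n_sp],
            sp_pop[:n_sp], truncated)


@dataclass
class NetworkResult:
    """Output of one spiking-network simulation."""

    raster_E: SpikeRaster
    raster_I: SpikeRaster
    rate_E: RateTrace
    rate_I: RateTrace
    adaptation_mean: np.ndarray   # pA, per time step
    seed: int
    dt: float


def simulate_network(neuron: NeuronParams, net: NetworkParams,
                     stimulus: Stimulus | StimulusWaveform | None = None,
                     duration: float = 1000.0, dt: float = 0.1,
                     seed: int = 0, record_spikes: bool = True,
                     ) -> NetworkResult:
    """Simulate the AdEx network for ``duration`` ms.

    The stimulus (pA) is added to the mean external drive of the excitatory
    population.  Connectivity, initial voltages (uniform in [V_r, V_T]) and
    the per-neuron noise are all derived from ``seed``; identical seeds give
    bit-identical results.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for d in (net.d_E, net.d_I):
        if d < dt:
            raise ValueError("delays must be at least one time step")
    n_steps = int(round(duration / dt))
    if stimulus is None:
        stimulus = ZeroStimulus()
    if isinstance(stimulus, Stimulus):
        wave = stimulus.sample(duration, dt)
    else:
        wave = stimulus
        if len(wave.values_pA) < n_steps:
            raise ValueError("stimulus shorter than the simulation window")
    mu_ext_E = np.full(n_steps, net.mu_ext_E) + wave.values_pA[:n_steps] / neuron.C
    mu_ext_I = np.full(n_steps, net.mu_ext_I)

    # connectivity: regenerated per simulation from the seed
    rng = np.random.default_rng(seed)
    conn_seeds = rng.integers(0, 2 ** 31 - 1, size=5)
    pres = {"EE": net.N_E, "IE": net.N_E, "EI": net.N_I, "II": net.N_I}
    posts = {"EE": net.N_E, "IE": net.N_I, "EI": net.N_E, "II": net.N_I}
    csr = {}
    for k, proj in enumerate(("EE", "IE", "EI", "II")):
        edges = _sample_in_edges(pres[proj], posts[proj], net.K_pre(proj),
                                 self_connections=False, seed=int(conn_seeds[k]))
        csr[proj] = _outgoing_csr(edges, pres[proj])

    J = np.array([net.J_EE, net.J_IE, net.J_EI, net.J_II])
    m = np.array([net.c_EE / abs(net.J_EE), net.c_IE / abs(net.J_IE),
                  net.c_EI / abs(net.J_EI), net.c_II / abs(net.J_II)])
    tau_s = np.array([net.tau_s_E, net.tau_s_E, net.tau_s_I, net.tau_s_I])
    spike_cap = int(net.N_E + net.N_I) * max(int(duration / 1000.0), 1) * 100 \
        + 100000

    out = _run_network(
        n_steps, dt, net.N_E, net.N_I,
        neuron.C, neuron.g_L, neuron.E_L, neuron.Delta_T, neuron.V_T,
        neuron.V_s, neuron.V_r, int(round(neuron.T_ref / dt)),
        neuron.a, neuron.b, neuron.E_A, neuron.tau_A,
        J, m, tau_s,
        int(round(net.d_E / dt)), int(round(net.d_I / dt)),
        mu_ext_E, mu_ext_I, net.sigma_ext,
        csr["EE"][0], csr["EE"][1], csr["IE"][0], csr["IE"][1],
        csr["EI"][0], csr["EI"][1], csr["II"][0], csr["II"][1],
        int(conn_seeds[4]), record_spikes, spike_cap)
    rate_E, rate_I, IA_mean, sp_id, sp_t, sp_pop, truncated = out
    if truncated:
        import warnings

        warnings.warn("spike record capacity exceeded; raster truncated")

    time = np.arange(n_steps) * dt
    is_E = sp_pop == 0
    return NetworkResult(
        raster_E=SpikeRaster(sp_id[is_E], sp_t[is_E], net.N_E, duration, "E"),
        raster_I=SpikeRaster(sp_id[~is_E], sp_t[~is_E], net.N_I, duration, "I"),
        rate_E=RateTrace(time, rate_E, "E"),
        rate_I=RateTrace(time, rate_I, "I"),
        adaptation_mean=IA_mean, seed=seed, dt=dt)


def population_rate(raster: SpikeRaster, dt: float) -> RateTrace:
    """Population rate from a raster: spikes in [t, t+dt) / (N dt), in Hz."""
    if raster.n_neurons <= 0:
        raise ValueError("raster has no neurons")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_bins = int(np.ceil(raster.duration / dt))
    counts, _ = np.histogram(raster.times,
                             bins=np.arange(n_bins + 1) * dt)
    rate = counts / (raster.n_neurons * dt * 1e-3)
    return RateTrace(np.arange(n_bins) * dt, rate, raster.population)
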