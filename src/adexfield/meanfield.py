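"""Low-dimensional cascade model of the delay-coupled E-I population pair.

The state of each population is summarized by the mean membrane current
``mu_alpha`` (mV/ms), which relaxes toward the sum of synaptic and external
drive with the input-dependent timescale ``tau_alpha(mu, sigma)`` read from
the precomputed transfer table at every step.  The instantaneous population
rate is the static nonlinearity ``r_alpha = Phi(mu_alpha, sigma_alpha)``;
for the excitatory population the mean adaptation current is subtracted from
the abscissa, ``r_E = Phi(mu_E - I_A/C, sigma_E)``.

Synaptic activity per projection (EE, IE, EI, II) is tracked by its mean
``s_bar`` in [0, 1] and variance, driven by the delayed presynaptic rate;
the membrane-current variance ``sigma_alpha^2`` follows algebraically from
the synaptic variances plus the external noise floor.  Integration is
forward Euler (the relaxation factor dt/tau saturates at 1 so that very
fast table timescales cannot destabilize the scheme).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .params import NetworkParams, NeuronParams, PROJECTIONS
from .stimuli import Stimulus, StimulusWaveform, ZeroStimulus
from .transfer import TransferTable, _bilinear

#: projection index order used by the kernel: target/source pairs
_PROJ = ("EE", "IE", "EI", "II")


@dataclass
class MeanFieldTrace:
    """Time-resolved output of the cascade model (rates in Hz)."""

    time: np.ndarray
    r_E: np.ndarray
    r_I: np.ndarray
    mu_E: np.ndarray
    mu_I: np.ndarray
    V_E: np.ndarray
    V_I: np.ndarray
    I_A: np.ndarray
    sigma_E: np.ndarray
    sigma_I: np.ndarray

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def after(self, t_ms: float) -> "MeanFieldTrace":
        """Sub-trace for time >= t_ms (transient removal)."""
        i = int(np.searchsorted(self.time, t_ms))
        return MeanFieldTrace(*(getattr(self, f)[i:] for f in (
            "time", "r_E", "r_I", "mu_E", "mu_I", "V_E", "V_I", "I_A",
            "sigma_E", "sigma_I")))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "time_ms": self.time, "rE_Hz": self.r_E, "rI_Hz": self.r_I,
            "muE": self.mu_E, "muI": self.mu_I, "VE_mV": self.V_E,
            "VI_mV": self.V_I, "IA_pA": self.I_A,
            "sigmaE": self.sigma_E, "sigmaI": self.sigma_I,
        })


@njit(cache=True)
def _integrate(n_steps, dt, mu_grid, sig_grid, Phi, Vm, Tau,
               J, m, Kpre, tau_s, delays_steps, tau_m,
               a, b, E_A, tau_A, C, sigma_ext,
               mu_ext_E, mu_ext_I,
               mu0_E, mu0_I):
    # projection order EE, IE, EI, II; source pop: E,E,I,I; target: E,I,E,I
    src = np.array([0, 0, 1, 1])
    tgt = np.array([0, 1, 0, 1])
    sbar = np.zeros(4)
    svar = np.zeros(4)
    muA = np.array([mu0_E, mu0_I])
    IA = 0.0
    max_delay = int(max(delays_steps[0], delays_steps[1]))
    hist_len = max_delay + 1
    # rate history ring buffers, initialized from the initial lookup
    rhist = np.zeros((2, hist_len))
    sigma0 = sigma_ext
    r0_E = _bilinear(mu_grid, sig_grid, Phi, mu0_E, sigma0)
    r0_I = _bilinear(mu_grid, sig_grid, Phi, mu0_I, sigma0)
    for k in range(hist_len):
        rhist[0, k] = r0_E
        rhist[1, k] = r0_I

    out = np.zeros((9, n_steps))
    for t in range(n_steps):
        head = t % hist_len
        # delayed rates per projection (delay set by the target population)
        rdel = np.empty(4)
        for p in range(4):
            d = delays_steps[tgt[p]]
            rdel[p] = rhist[src[p], (t - d) % hist_len]
        # membrane-current variance per population
        sig2 = np.empty(2)
        for al in range(2):
            acc = sigma_ext * sigma_ext
            for p in range(4):
                if tgt[p] == al:
                    z1 = m[p] * Kpre[p] * rdel[p] * tau_s[p]
                    acc += (2.0 * J[p] * J[p] * svar[p] * tau_s[p] * tau_m
                            / ((1.0 + z1) * tau_m + tau_s[p]))
            sig2[al] = acc
        sigE = np.sqrt(sig2[0])
        sigI = np.sqrt(sig2[1])
        # transfer-function lookups (E uses the adaptation-corrected input)
        mu_eff_E = muA[0] - IA / C
        rE = _bilinear(mu_grid, sig_grid, Phi, mu_eff_E, sigE)
        VE = _bilinear(mu_grid, sig_grid, Vm, mu_eff_E, sigE)
        tauE = _bilinear(mu_grid, sig_grid, Tau, mu_eff_E, sigE)
        rI = _bilinear(mu_grid, sig_grid, Phi, muA[1], sigI)
        VI = _bilinear(mu_grid, sig_grid, Vm, muA[1], sigI)
        tauI = _bilinear(mu_grid, sig_grid, Tau, muA[1], sigI)
        rhist[0, head] = rE
        rhist[1, head] = rI

        out[0, t] = rE
        out[1, t] = rI
        out[2, t] = muA[0]
        out[3, t] = muA[1]
        out[4, t] = VE
        out[5, t] = VI
        out[6, t] = IA
        out[7, t] = sigE
        out[8, t] = sigI
        if not (np.isfinite(rE) and np.isfinite(rI)
                and np.isfinite(muA[0]) and np.isfinite(muA[1])):
            raise FloatingPointError("mean-field integration diverged")

        # Euler updates
        mu_syn_E = J[0] * sbar[0] + J[2] * sbar[2]
        mu_syn_I = J[1] * sbar[1] + J[3] * sbar[3]
        aE = dt / tauE
        aI = dt / tauI
        if aE > 1.0:
            aE = 1.0
        if aI > 1.0:
            aI = 1.0
        muA[0] += aE * (mu_syn_E + mu_ext_E[t] - muA[0])
        muA[1] += aI * (mu_syn_I + mu_ext_I[t] - muA[1])
        for p in range(4):
            reff = m[p] * Kpre[p] * rdel[p]  # effective input rate, kHz
            rho = m[p] * reff
            sbar_new = sbar[p] + dt * (-sbar[p] / tau_s[p]
                                       + (1.0 - sbar[p]) * reff)
            svar_new = svar[p] + dt * (
                rho * (1.0 - sbar[p]) ** 2
                + (rho - 2.0 * (reff + 1.0 / tau_s[p])) * svar[p])
            if sbar_new < 0.0:
                sbar_new = 0.0
            elif sbar_new > 1.0:
                sbar_new = 1.0
            if svar_new < 0.0:
                svar_new = 0.0
            sbar[p] = sbar_new
            svar[p] = svar_new
        IA += dt * ((a * (VE - E_A) - IA) / tau_A + b * rE)
    return out


def simulate_meanfield(neuron: NeuronParams, net: NetworkParams,
                       tables: TransferTable,
                       stimulus: Stimulus | StimulusWaveform | None = None,
                       duration: float = 5000.0, dt: float = 0.05,
                       ) -> MeanFieldTrace:
    """Integrate the cascade model for ``duration`` ms with step ``dt`` ms.

    The stimulus (pA) is added to the external drive of the excitatory
    population only.  Initial conditions: mu at the external drive, synaptic
    means/variances and the adaptation current at zero, flat rate history.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    max_delay = max(net.d_E, net.d_I)
    if duration < max_delay:
        raise ValueError("duration must exceed the maximum delay")
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

    J = np.array([net.J(p) for p in _PROJ])
    m = np.array([net.c(p) / abs(net.J(p)) for p in _PROJ])
    Kpre = np.array([float(net.K_pre(p)) for p in _PROJ])
    tau_s = np.array([net.tau_s(p) for p in _PROJ])
    delays_steps = np.array([int(round(net.d_E / dt)), int(round(net.d_I / dt))])

    out = _integrate(
        n_steps, dt, tables.grid.mu_values, tables.grid.sigma_values,
        tables.Phi, tables.Vmean, tables.tau,
        J, m, Kpre, tau_s, delays_steps, neuron.tau_m,
        neuron.a, neuron.b, neuron.E_A, neuron.tau_A, neuron.C,
        net.sigma_ext, mu_ext_E, mu_ext_I,
        net.mu_ext_E, net.mu_ext_I)

    time = np.arange(n_steps) * dt
    return MeanFieldTrace(
        time=time, r_E=out[0] * 1e3, r_I=out[1] * 1e3,
        mu_E=out[2], mu_I=out[3], V_E=out[4], V_I=out[5],
        I_A=out[6], sigma_E=out[7], sigma_I=out[8])


def synaptic_steady_state(reff_kHz: float, tau_s: float) -> float:
    """Fixed point of the mean synaptic activity for a constant effective
    input rate: s_bar* = tau_s r / (1 + tau_s r)."""
    return tau_s * reff_kHz / (1.0 + tau_s * reff_kHz)


# ---------------------------------------------------------------------------
# single-step reference implementation


@dataclass
class MeanFieldState:
    """Explicit state of the cascade model for step-wise integration.

    ``s_bar`` and ``sigma2_s`` are indexed by projection (EE, IE, EI, II);
    ``rate_history`` is a (2, L) ring buffer of past E and I rates (kHz)
    covering the maximum delay, with ``step`` counting elapsed steps.
    """

    mu_E: float
    mu_I: float
    I_A: float
    s_bar: np.ndarray
    sigma2_s: np.ndarray
    rate_history: np.ndarray
    step: int = 0


def initial_state(neuron: NeuronParams, net: NetworkParams,
                  tables: TransferTable, dt: float) -> MeanFieldState:
    """Standard initialization: mu at the external drive, synaptic state and
    adaptation at zero, flat rate history from the initial lookup."""
    hist_len = int(max(round(net.d_E / dt), round(net.d_I / dt))) + 1
    r0_E, _, _ = tables.lookup(net.mu_ext_E, net.sigma_ext)
    r0_I, _, _ = tables.lookup(net.mu_ext_I, net.sigma_ext)
    hist = np.empty((2, hist_len))
    hist[0] = r0_E
    hist[1] = r0_I
    return MeanFieldState(net.mu_ext_E, net.mu_ext_I, 0.0, np.zeros(4),
                          np.zeros(4), hist)


def step_meanfield(state: MeanFieldState, tables: TransferTable,
                   neuron: NeuronParams, net: NetworkParams,
                   stim_pA: float, dt: float) -> MeanFieldState:
    """One forward-Euler update of the cascade equations (in place).

    A plain-Python mirror of the compiled integrator, following the same
    operation order; integrating step by step reproduces
    :func:`simulate_meanfield` exactly.  Returns the mutated state.
    """
    src = (0, 0, 1, 1)
    tgt = (0, 1, 0, 1)
    J = np.array([net.J(p) for p in _PROJ])
    m = np.array([net.c(p) / abs(net.J(p)) for p in _PROJ])
    Kpre = np.array([float(net.K_pre(p)) for p in _PROJ])
    tau_s = np.array([net.tau_s(p) for p in _PROJ])
    delays = (int(round(net.d_E / dt)), int(round(net.d_I / dt)))
    hist_len = state.rate_history.shape[1]
    t = state.step
    mu = [state.mu_E, state.mu_I]

    rdel = np.empty(4)
    for p in range(4):
        rdel[p] = state.rate_history[src[p], (t - delays[tgt[p]]) % hist_len]
    sig = np.empty(2)
    for al in range(2):
        acc = net.sigma_ext ** 2
        for p in range(4):
            if tgt[p] == al:
                z1 = m[p] * Kpre[p] * rdel[p] * tau_s[p]
                acc += (2.0 * J[p] ** 2 * state.sigma2_s[p] * tau_s[p]
                        * neuron.tau_m
                        / ((1.0 + z1) * neuron.tau_m + tau_s[p]))
        sig[al] = np.sqrt(acc)
    mu_eff_E = mu[0] - state.I_A / neuron.C
    rE, VE, tauE = tables.lookup(mu_eff_E, sig[0])
    rI, _, tauI = tables.lookup(mu[1], sig[1])
    state.rate_history[0, t % hist_len] = rE
    state.rate_history[1, t % hist_len] = rI

    mu_syn = (J[0] * state.s_bar[0] + J[2] * state.s_bar[2],
              J[1] * state.s_bar[1] + J[3] * state.s_bar[3])
    aE = min(dt / tauE, 1.0)
    aI = min(dt / tauI, 1.0)
    state.mu_E += aE * (mu_syn[0] + net.mu_ext_E + stim_pA / neuron.C
                        - state.mu_E)
    state.mu_I += aI * (mu_syn[1] + net.mu_ext_I - state.mu_I)
    for p in range(4):
        reff = m[p] * Kpre[p] * rdel[p]
        rho = m[p] * reff
        s_new = state.s_bar[p] + dt * (-state.s_bar[p] / tau_s[p]
                                       + (1.0 - state.s_bar[p]) * reff)
        v_new = state.sigma2_s[p] + dt * (
            rho * (1.0 - state.s_bar[p]) ** 2
            + (rho - 2.0 * (reff + 1.0 / tau_s[p])) * state.sigma2_s[p])
        state.s_bar[p] = min(max(s_new, 0.0), 1.0)
        state.sigma2_s[p] = max(v_new, 0.0)
    state.I_A += dt * ((neuron.a * (VE - neuron.E_A) - state.I_A)
                       / neuron.tau_A + neuron.b * rE)
    state.step += 1
    return state
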