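"""State classification, bifurcation scans, entrainment and phase locking.

The dynamical state of the E-I system at a given pair of background drives
is classified with a stimulus-probe protocol: a slowly decaying negative
kick places the system in the basin of the low-activity state, the
post-kick window is tested for oscillations (Welch spectrum; oscillating if
the dominant frequency exceeds 0.1 Hz and its power density exceeds 1), and
a subsequent positive kick probes for a coexisting high-activity branch
(bistable if the relaxed mean rates after the two kicks differ by more than
10 Hz).  Phase locking between a sinusoidal stimulus and the population
rate is quantified by the Kuramoto order parameter of their two
instantaneous phases; a constant R(t) (low standard deviation) means the
phase difference stays fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, welch

from .meanfield import simulate_meanfield
from .network import RateTrace, simulate_network
from .params import NetworkParams, NeuronParams, drive_from_nA
from .stimuli import Stimulus, bistability_probe, sinusoid

#: oscillation-classification thresholds
OSC_FREQ_MIN_HZ = 0.1
OSC_POWER_MIN = 1.0
#: bistability threshold on the relaxed rate difference
BISTABLE_DIFF_HZ = 10.0
#: up/down split on the relaxed mean rate
UP_RATE_HZ = 10.0
#: oscillatory cells slower than this are attributed to the adaptation loop
SLOW_LC_MAX_HZ = 6.0
#: phase-locking decision threshold on std(R)
LOCKED_STD_MAX = 0.05


# ---------------------------------------------------------------------------
# spectra


@dataclass
class SpectrumResult:
    frequency_Hz: np.ndarray
    power: np.ndarray
    dominant_frequency: float   # NaN for a constant trace
    dominant_power: float


def welch_spectrum(rate_Hz: np.ndarray, dt_ms: float,
                   window_ms: float = 500.0) -> SpectrumResult:
    """Welch periodogram of a rate trace with a Hanning window."""
    rate_Hz = np.asarray(rate_Hz, float)
    nper = int(round(window_ms / dt_ms))
    if len(rate_Hz) < nper:
        raise ValueError("trace shorter than the Welch window")
    f, P = welch(rate_Hz, fs=1000.0 / dt_ms, window="hann", nperseg=nper)
    pos = f > 0
    if not np.any(P[pos] > 0):
        return SpectrumResult(f, P, float("nan"), 0.0)
    i = np.argmax(P[pos])
    return SpectrumResult(f, P, float(f[pos][i]), float(P[pos][i]))


def classify_oscillation(spectrum: SpectrumResult,
                         f_min: float = OSC_FREQ_MIN_HZ,
                         power_min: float = OSC_POWER_MIN) -> bool:
    """Oscillating iff the dominant frequency and its power density exceed
    the two thresholds."""
    return (np.isfinite(spectrum.dominant_frequency)
            and spectrum.dominant_frequency > f_min
            and spectrum.dominant_power > power_min)


# ---------------------------------------------------------------------------
# backends: closures mapping (stimulus, duration) -> excitatory RateTrace


Backend = Callable[[Optional[Stimulus], float], RateTrace]


def meanfield_backend(neuron: NeuronParams, net: NetworkParams, tables,
                      dt: float = 0.05) -> Backend:
    def run(stimulus, duration):
        tr = simulate_meanfield(neuron, net, tables, stimulus=stimulus,
                                duration=duration, dt=dt)
        return RateTrace(tr.time, tr.r_E, "E")
    run.dt = dt  # type: ignore[attr-defined]
    return run


def network_backend(neuron: NeuronParams, net: NetworkParams,
                    dt: float = 0.1, seed: int = 0) -> Backend:
    def run(stimulus, duration):
        res = simulate_network(neuron, net, stimulus=stimulus,
                               duration=duration, dt=dt, seed=seed,
                               record_spikes=False)
        return res.rate_E
    run.dt = dt  # type: ignore[attr-defined]
    return run


# ---------------------------------------------------------------------------
# state classification


@dataclass
class StateLabel:
    label: str                  # down | up | bistable | LC_EI | LC_aE
    dominant_frequency: float   # Hz, NaN if not oscillatory
    max_rate: float             # Hz, max excitatory rate in the probe window


@dataclass
class ProbeProtocol:
    """Timing of the two-kick classification protocol (ms).

    The slow variant stretches the windows so that sub-hertz adaptation
    oscillations are resolvable (2 s Welch window on a 4 s segment).
    """

    kick_pA: float = 300.0
    neg_onset: float = 500.0
    plateau: float = 500.0
    decay_tau: float = 500.0
    osc_window: Tuple[float, float] = (3000.0, 4000.0)
    mean1_window: Tuple[float, float] = (3000.0, 4000.0)
    pos_onset: float = 4000.0
    mean2_window: Tuple[float, float] = (6500.0, 7500.0)
    duration: float = 7500.0
    welch_ms: float = 500.0

    @classmethod
    def slow(cls) -> "ProbeProtocol":
        return cls(osc_window=(3000.0, 7000.0), mean1_window=(6000.0, 7000.0),
                   pos_onset=7000.0, mean2_window=(11000.0, 12000.0),
                   duration=12000.0, welch_ms=2000.0)


def _window(trace: RateTrace, lo: float, hi: float) -> np.ndarray:
    sel = (trace.time >= lo) & (trace.time < hi)
    return trace.rate[sel]


def classify_state(backend: Backend, protocol: ProbeProtocol | None = None,
                   adaptation: bool = False) -> StateLabel:
    """Run the two-kick probe through a backend and label the state."""
    protocol = protocol or (ProbeProtocol.slow() if adaptation
                            else ProbeProtocol())
    probe = bistability_probe(protocol.kick_pA, neg_onset=protocol.neg_onset,
                              pos_onset=protocol.pos_onset,
                              plateau=protocol.plateau,
                              decay_tau=protocol.decay_tau)
    trace = backend(probe, protocol.duration)
    dt = trace.dt
    seg = _window(trace, *protocol.osc_window)
    spec = welch_spectrum(seg, dt, protocol.welch_ms)
    oscillating = classify_oscillation(spec)
    if oscillating and spec.dominant_power < 2.0 * OSC_POWER_MIN:
        # near-threshold power: re-test on the later half of the window to
        # avoid misreading a slow down->up transition as an oscillation
        mid = 0.5 * (protocol.osc_window[0] + protocol.osc_window[1])
        late = _window(trace, mid, protocol.osc_window[1])
        if len(late) * dt >= protocol.welch_ms:
            spec = welch_spectrum(late, dt, protocol.welch_ms)
            oscillating = classify_oscillation(spec)
    max_rate = float(seg.max()) if len(seg) else float("nan")
    if oscillating:
        slow = spec.dominant_frequency < SLOW_LC_MAX_HZ
        label = "LC_aE" if (adaptation and slow) else "LC_EI"
        return StateLabel(label, spec.dominant_frequency, max_rate)
    m1 = float(_window(trace, *protocol.mean1_window).mean())
    w2 = _window(trace, *protocol.mean2_window)
    m2 = float(w2.mean())
    spec2 = welch_spectrum(w2, dt, min(protocol.welch_ms, len(w2) * dt))
    if m2 - m1 > BISTABLE_DIFF_HZ and not classify_oscillation(spec2):
        return StateLabel("bistable", float("nan"), max(max_rate, m2))
    mean_rate = 0.5 * (m1 + m2)
    label = "up" if mean_rate > UP_RATE_HZ else "down"
    return StateLabel(label, float("nan"), max(max_rate, m2))


def classify_bistability(backend: Backend,
                         protocol: ProbeProtocol | None = None) -> bool:
    """True iff the two-kick probe relaxes to rates differing by > 10 Hz
    with neither phase oscillating."""
    return classify_state(backend, protocol).label == "bistable"


# ---------------------------------------------------------------------------
# bifurcation scans


@dataclass
class BifurcationDiagram:
    mu_E_nA: np.ndarray            # grid axis, C*mu_E^ext in nA
    mu_I_nA: np.ndarray
    labels: np.ndarray             # (n_E, n_I) strings
    dominant_frequency: np.ndarray
    max_rate: np.ndarray
    backend: str = "meanfield"
    a: float = 0.0
    b: float = 0.0
    failures: List[Tuple[int, int, str]] = field(default_factory=list)

    def cells(self, label: str) -> np.ndarray:
        return self.labels == label

    def to_frame(self):
        import pandas as pd

        ee, ii = np.meshgrid(self.mu_E_nA, self.mu_I_nA, indexing="ij")
        return pd.DataFrame({
            "muE_nA": ee.ravel(), "muI_nA": ii.ravel(),
            "label": self.labels.ravel(),
            "dom_freq_Hz": self.dominant_frequency.ravel(),
            "max_rate_Hz": self.max_rate.ravel(),
        })


def scan_bifurcation(backend_factory: Callable[[float, float], Backend],
                     mu_E_nA: Sequence[float], mu_I_nA: Sequence[float],
                     adaptation: bool = False,
                     protocol: ProbeProtocol | None = None,
                     backend_name: str = "meanfield",
                     a: float = 0.0, b: float = 0.0) -> BifurcationDiagram:
    """Classify every cell of a (mu_E, mu_I) grid of external drives.

    ``backend_factory(muE_nA, muI_nA)`` must return a backend closure for
    that drive pair.  Per-cell failures are recorded and the scan continues.
    """
    mu_E_nA = np.asarray(mu_E_nA, float)
    mu_I_nA = np.asarray(mu_I_nA, float)
    shape = (len(mu_E_nA), len(mu_I_nA))
    labels = np.full(shape, "failed", dtype=object)
    domf = np.full(shape, np.nan)
    maxr = np.full(shape, np.nan)
    failures: List[Tuple[int, int, str]] = []
    for i, e in enumerate(mu_E_nA):
        for j, g in enumerate(mu_I_nA):
            try:
                st = classify_state(backend_factory(float(e), float(g)),
                                    protocol, adaptation=adaptation)
                labels[i, j] = st.label
                domf[i, j] = st.dominant_frequency
                maxr[i, j] = st.max_rate
            except Exception as exc:  # noqa: BLE001 - per-cell isolation
                failures.append((i, j, repr(exc)))
    return BifurcationDiagram(mu_E_nA, mu_I_nA, labels, domf, maxr,
                              backend=backend_name, a=a, b=b,
                              failures=failures)


def meanfield_scan_factory(neuron: NeuronParams, net: NetworkParams, tables,
                           dt: float = 0.05) -> Callable[[float, float], Backend]:
    def factory(muE_nA: float, muI_nA: float) -> Backend:
        drives = net.with_drive(drive_from_nA(muE_nA, neuron),
                                drive_from_nA(muI_nA, neuron))
        return meanfield_backend(neuron, drives, tables, dt=dt)
    return factory


def network_scan_factory(neuron: NeuronParams, net: NetworkParams,
                         dt: float = 0.1, seed: int = 0,
                         ) -> Callable[[float, float], Backend]:
    def factory(muE_nA: float, muI_nA: float) -> Backend:
        drives = net.with_drive(drive_from_nA(muE_nA, neuron),
                                drive_from_nA(muI_nA, neuron))
        return network_backend(neuron, drives, dt=dt, seed=seed)
    return factory


# ---------------------------------------------------------------------------
# instantaneous phase and phase locking


def instantaneous_phase(signal: np.ndarray, dt_ms: float,
                        smooth_sd_ms: float = 5.0) -> np.ndarray:
    """Peak-interval phase in [0, 2 pi), NaN before the second peak.

    The trace is Gaussian-smoothed, maxima are detected with a minimum
    separation of half the dominant period, and the phase between peak n and
    the next advances as 2 pi (t - t_n)/(t_n - t_{n-1}).
    """
    x = np.asarray(signal, float)
    if smooth_sd_ms > 0:
        x = gaussian_filter1d(x, smooth_sd_ms / dt_ms)
    span = x.max() - x.min()
    if span <= 0:
        raise ValueError("constant signal has no phase")
    # minimum peak distance from the dominant period
    win = min(len(x) * dt_ms / 2.0, 2000.0)
    spec = welch_spectrum(x, dt_ms, window_ms=win)
    if np.isfinite(spec.dominant_frequency) and spec.dominant_frequency > 0:
        dist = max(int(0.5 * 1000.0 / spec.dominant_frequency / dt_ms), 1)
    else:
        dist = 1
    peaks, _ = find_peaks(x, distance=dist, prominence=0.1 * span)
    if len(peaks) < 3:
        raise ValueError(f"need >= 3 peaks for phase extraction, got {len(peaks)}")
    phase = np.full(len(x), np.nan)
    idx = np.arange(len(x))
    for k in range(1, len(peaks)):
        period = peaks[k] - peaks[k - 1]
        hi = peaks[k + 1] if k + 1 < len(peaks) else len(x)
        seg = idx[peaks[k]:hi]
        phase[seg] = 2.0 * np.pi * (seg - peaks[k]) / period
    return np.mod(phase, 2.0 * np.pi)


def kuramoto_order(phases: np.ndarray) -> np.ndarray | float:
    """Modulus of the mean unit phasor over oscillators.

    ``phases`` is (n_osc,) for a single time point or (n_osc, n_t) for a
    series; the result is a scalar or an R(t) array in [0, 1].
    """
    phases = np.asarray(phases, float)
    if phases.shape[0] < 2:
        raise ValueError("need at least two oscillators")
    R = np.abs(np.mean(np.exp(1j * phases), axis=0))
    return float(R) if R.ndim == 0 else R


@dataclass
class PhaseLockResult:
    time: np.ndarray
    R: np.ndarray
    locking_index: float   # std of R(t) for t > t_min; low = locked
    locked: bool


def phase_locking_index(rate: RateTrace, stim_values: np.ndarray,
                        t_min_ms: float = 1500.0,
                        smooth_sd_ms: float = 5.0) -> PhaseLockResult:
    """Kuramoto order parameter of the stimulus/rate phase pair.

    ``stim_values`` must be sampled on the same grid as ``rate``.  The
    locking index is the temporal standard deviation of R(t) after the
    transient; a constant R (index below 0.05) means locked.
    """
    dt = rate.dt
    ph_r = instantaneous_phase(rate.rate, dt, smooth_sd_ms)
    ph_s = instantaneous_phase(np.asarray(stim_values, float), dt, smooth_sd_ms)
    valid = np.isfinite(ph_r) & np.isfinite(ph_s)
    R = np.full(len(ph_r), np.nan)
    R[valid] = kuramoto_order(np.vstack([ph_s[valid], ph_r[valid]]))
    late = valid & (rate.time > t_min_ms)
    if late.sum() < 10:
        raise ValueError("too few valid samples after the transient")
    index = float(np.std(R[late]))
    return PhaseLockResult(rate.time, R, index, index < LOCKED_STD_MAX)


# ---------------------------------------------------------------------------
# entrainment


@dataclass
class EntrainmentResult:
    f_ext_Hz: np.ndarray
    dominant_frequency: np.ndarray      # per stimulation frequency
    spectra: List[SpectrumResult]
    failures: List[Tuple[float, str]]

    def entrained_mask(self, tol_Hz: float = 0.6) -> np.ndarray:
        """1:1 entrainment: output dominant frequency equals f_ext."""
        return np.abs(self.dominant_frequency - self.f_ext_Hz) <= tol_Hz

    def upper_edge(self, tol_Hz: float = 0.6) -> float:
        """Largest stimulation frequency still 1:1 entrained."""
        mask = self.entrained_mask(tol_Hz)
        if not mask.any():
            return float("nan")
        return float(self.f_ext_Hz[mask].max())

    def power_matrix(self, log_normalized: bool = True) -> np.ndarray:
        n_f = min(len(s.power) for s in self.spectra)
        M = np.vstack([s.power[:n_f] for s in self.spectra])
        if log_normalized:
            L = np.log10(M + 1e-12)
            L -= L.min()
            if L.max() > 0:
                L /= L.max()
            return L
        return M


def entrainment_sweep(backend: Backend, f_ext_Hz: Sequence[float],
                      amplitude_pA: float, duration: float = 6000.0,
                      transient_ms: float = 1000.0,
                      welch_ms: float = 1000.0) -> EntrainmentResult:
    """Drive the system with a sinusoid at each frequency and measure the
    spectrum of the post-transient excitatory rate (stimulus switched on
    after the transient)."""
    if amplitude_pA < 0:
        raise ValueError("amplitude must be non-negative")
    f_ext_Hz = np.asarray(f_ext_Hz, float)
    doms = np.full(len(f_ext_Hz), np.nan)
    spectra: List[SpectrumResult] = []
    failures: List[Tuple[float, str]] = []
    for k, f in enumerate(f_ext_Hz):
        try:
            stim = sinusoid(amplitude_pA, float(f), onset=transient_ms) \
                if amplitude_pA > 0 else None
            trace = backend(stim, duration)
            seg = trace.after(transient_ms)
            spec = welch_spectrum(seg.rate, trace.dt, welch_ms)
            spectra.append(spec)
            doms[k] = spec.dominant_frequency
        except Exception as exc:  # noqa: BLE001
            failures.append((float(f), repr(exc)))
            spectra.append(SpectrumResult(np.array([]), np.array([]),
                                          float("nan"), 0.0))
    return EntrainmentResult(f_ext_Hz, doms, spectra, failures)
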