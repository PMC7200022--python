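"""Steady-state transfer functions of an EIF population under white noise.

For a population of uncoupled EIF neurons (AdEx with a = b = 0) driven by a
white-noise current with mean ``mu`` (mV/ms) and intensity ``sigma``
(mV ms^-1/2), three quantities are precomputed on a (mu, sigma) grid:

* ``Phi(mu, sigma)`` - stationary population firing rate (kHz internally),
* ``Vmean(mu, sigma)`` - stationary mean membrane potential (mV),
* ``tau(mu, sigma)`` - timescale of the exponential kernel that best
  approximates the linear rate response to modulations of ``mu`` (ms).

All three are obtained by threshold integration of the stationary and
linearly perturbed Fokker-Planck equations: the flux/density pair is
integrated backward in voltage from the absorbing spike cutoff ``V_s`` down
to a reflecting lower bound, with the outflux re-injected at the reset
``V_r`` (delayed by the refractory period in the modulated problem).  The
timescale is a least-squares Lorentzian fit |r1(0)|/sqrt(1+(2 pi f tau)^2)
to the rate-response amplitude at log-spaced modulation frequencies.

The resulting grids are bundled in a :class:`TransferTable` with bilinear
lookup and exact (bit-level) serialization.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple

import numpy as np
from numba import njit
from scipy.optimize import minimize_scalar

from .params import NeuronParams, params_hash

logger = logging.getLogger(__name__)

#: voltage grid for the threshold integration (mV)
V_LB = -200.0
DV = 0.01

#: modulation frequencies for the timescale fit (Hz); 0 is the static gain
TAU_FIT_FREQS = np.concatenate([[0.0], np.logspace(-1, 2, 20)])

#: below this stationary rate (kHz) the response fit is degenerate and the
#: timescale falls back to the membrane time constant
RATE_FLOOR = 1e-8


@dataclass(frozen=True)
class GridSpec:
    """Axes of the (mu, sigma) lookup grid."""

    mu_values: np.ndarray
    sigma_values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "mu_values", np.asarray(self.mu_values, float))
        object.__setattr__(self, "sigma_values", np.asarray(self.sigma_values, float))
        for name in ("mu_values", "sigma_values"):
            v = getattr(self, name)
            if v.ndim != 1 or len(v) < 2 or np.any(np.diff(v) <= 0):
                raise ValueError(f"{name} must be strictly increasing, length >= 2")
        if self.sigma_values[0] <= 0:
            raise ValueError("sigma grid must be positive")

    @classmethod
    def default(cls) -> "GridSpec":
        """mu in [-2, 6] mV/ms step 0.05; sigma 30 log-spaced in [0.05, 5]."""
        return cls(np.round(np.arange(-2.0, 6.0 + 1e-9, 0.05), 10),
                   np.logspace(np.log10(0.05), np.log10(5.0), 30))


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _drift(V, mu, E_L, tau_m, Delta_T, V_T):
    return (E_L - V) / tau_m + (Delta_T / tau_m) * np.exp((V - V_T) / Delta_T) + mu


@njit(cache=True)
def _stationary_kernel(mu_arr, sigma, E_L, tau_m, Delta_T, V_T, V_r, T_ref,
                       V_s):
    """Backward threshold integration of the stationary Fokker-Planck flux.

    Returns (rate kHz, mean voltage mV, normalized density p0) per mu.
    """
    n = int(round((V_s - V_LB) / DV)) + 1
    nmu = mu_arr.shape[0]
    rates = np.zeros(nmu)
    vmeans = np.zeros(nmu)
    ptil = np.zeros((nmu, n))
    D = 0.5 * sigma * sigma
    for im in range(nmu):
        mu = mu_arr[im]
        p = 0.0
        I1 = 0.0
        IV = 0.0
        overflowed = False
        ptil[im, n - 1] = 0.0
        for k in range(n - 1, 0, -1):
            Vk = V_LB + k * DV
            Vmid = Vk - 0.5 * DV
            j = 1.0 if Vmid > V_r else 0.0
            F = _drift(Vmid, mu, E_L, tau_m, Delta_T, V_T)
            G = F / D
            gh = G * DV
            if np.abs(gh) > 1e-10:
                e = np.exp(-gh)
                p = p * e + (j / F) * (1.0 - e)
            else:
                p = p + (j - F * p) * DV / D
            if p > 1e280:
                p *= 1e-200
                I1 *= 1e-200
                IV *= 1e-200
                overflowed = True
            ptil[im, k - 1] = p
            I1 += p * DV
            IV += p * Vmid * DV
        if overflowed:
            rates[im] = 0.0
            vmeans[im] = IV / I1
        else:
            rates[im] = 1.0 / (T_ref + I1)
            vmeans[im] = (IV + T_ref * V_r) / (I1 + T_ref)
        # re-normalize the stored density to unit probability mass so the
        # perturbation kernel can use it directly as p0
        norm = I1 + (0.0 if overflowed else T_ref)
        for k in range(n):
            ptil[im, k] /= norm
    return rates, vmeans, ptil


@njit(cache=True)
def _response_kernel(mu_arr, sigma, rates, p0, omegas,
                     E_L, tau_m, Delta_T, V_T, V_r, T_ref):
    """Linear rate response r1(omega) to a unit modulation of mu.

    Two backward integrations per (mu, omega): a homogeneous solution with
    unit outflux at V_s (re-injected at V_r with the refractory delay) and an
    inhomogeneous one sourced by the stationary density p0.  The modulated
    rate follows from requiring zero flux at the lower bound.
    """
    n = p0.shape[1]
    nmu = mu_arr.shape[0]
    nw = omegas.shape[0]
    resp = np.zeros((nmu, nw), dtype=np.complex128)
    D = 0.5 * sigma * sigma
    for im in range(nmu):
        if rates[im] < RATE_FLOOR:
            continue
        mu = mu_arr[im]
        for iw in range(nw):
            w = omegas[iw]
            reinj = np.exp(-1j * w * T_ref)
            ph = 0.0 + 0.0j
            jh = 1.0 + 0.0j
            pi_ = 0.0 + 0.0j
            ji = 0.0 + 0.0j
            crossed_reset = False
            for k in range(n - 1, 0, -1):
                Vk = V_LB + k * DV
                Vmid = Vk - 0.5 * DV
                F = _drift(Vmid, mu, E_L, tau_m, Delta_T, V_T)
                G = F / D
                gh = G * DV
                src = p0[im, k]  # stationary density, source of the i-problem
                if (not crossed_reset) and Vmid <= V_r:
                    # outflux re-injected at the reset, delayed by T_ref
                    jh = jh - reinj
                    crossed_reset = True
                if np.abs(gh) > 1e-10:
                    e = np.exp(-gh)
                    ph_new = ph * e + (jh / F) * (1.0 - e)
                    pi_new = pi_ * e + ((ji - src) / F) * (1.0 - e)
                else:
                    ph_new = ph + (jh - F * ph) * DV / D
                    pi_new = pi_ + ((ji - src) - F * pi_) * DV / D
                jh_new = jh + 1j * w * 0.5 * DV * (ph + ph_new)
                ji_new = ji + 1j * w * 0.5 * DV * (pi_ + pi_new)
                ph, jh = ph_new, jh_new
                pi_, ji = pi_new, ji_new
            resp[im, iw] = -ji / jh
    return resp


# ---------------------------------------------------------------------------
# public operations


def stationary_rate_and_voltage(neuron: NeuronParams, mu: float,
                                sigma: float) -> Tuple[float, float]:
    """Stationary firing rate (kHz) and mean membrane potential (mV) of an
    EIF neuron with white-noise input of mean ``mu`` and intensity ``sigma``.

    Includes the reset at V_r, the absorbing cutoff V_s and the refractory
    fraction rate*T_ref clamped at V_r.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    _check_eif(neuron)
    rates, vmeans, _ = _stationary_kernel(
        np.array([float(mu)]), float(sigma), neuron.E_L, neuron.tau_m,
        neuron.Delta_T, neuron.V_T, neuron.V_r, neuron.T_ref, neuron.V_s)
    if not (np.isfinite(rates[0]) and np.isfinite(vmeans[0])):
        raise FloatingPointError(
            f"threshold integration diverged at mu={mu}, sigma={sigma}")
    return float(rates[0]), float(vmeans[0])


def _static_gain(neuron: NeuronParams, mu_arr: np.ndarray, sigma: float,
                 dmu: float = 1e-3) -> np.ndarray:
    """dPhi/dmu by central difference: the f -> 0 limit of the rate response."""
    args = (float(sigma), neuron.E_L, neuron.tau_m, neuron.Delta_T,
            neuron.V_T, neuron.V_r, neuron.T_ref, neuron.V_s)
    hi, _, _ = _stationary_kernel(np.asarray(mu_arr, float) + dmu, *args)
    lo, _, _ = _stationary_kernel(np.asarray(mu_arr, float) - dmu, *args)
    return (hi - lo) / (2.0 * dmu)


def rate_response_amplitude(neuron: NeuronParams, mu: float, sigma: float,
                            freqs_Hz: np.ndarray = TAU_FIT_FREQS) -> np.ndarray:
    """|r1(f)|: amplitude of the linear rate response (kHz per mV/ms) to a
    sinusoidal modulation of the mean input at each frequency.

    At f = 0 the modulated threshold-integration problem is degenerate (the
    flux below the reset vanishes identically), so the static gain is taken
    as dPhi/dmu.
    """
    _check_eif(neuron)
    freqs_Hz = np.asarray(freqs_Hz, float)
    rates, _, p0 = _stationary_kernel(
        np.array([float(mu)]), float(sigma), neuron.E_L, neuron.tau_m,
        neuron.Delta_T, neuron.V_T, neuron.V_r, neuron.T_ref, neuron.V_s)
    out = np.empty(len(freqs_Hz))
    nonzero = freqs_Hz > 0
    omegas = 2e-3 * np.pi * freqs_Hz[nonzero]  # rad/ms
    resp = _response_kernel(np.array([float(mu)]), float(sigma), rates, p0,
                            omegas, neuron.E_L, neuron.tau_m, neuron.Delta_T,
                            neuron.V_T, neuron.V_r, neuron.T_ref)
    out[nonzero] = np.abs(resp[0])
    if np.any(~nonzero):
        out[~nonzero] = _static_gain(neuron, np.array([float(mu)]), sigma)[0]
    return out


def _fit_lorentzian_tau(freqs_Hz: np.ndarray, amp: np.ndarray,
                        tau_fallback: float) -> Tuple[float, bool]:
    """Fit amp(f) ~ amp(0)/sqrt(1+(2 pi f tau)^2); tau in ms.

    Returns (tau, ok).  Degenerate (flat or vanishing) responses fall back to
    ``tau_fallback``.
    """
    r0 = amp[0]
    if not np.isfinite(r0) or r0 <= 0 or np.any(~np.isfinite(amp)):
        return tau_fallback, False
    f = freqs_Hz[1:]
    y = amp[1:]

    def sse(tau_ms):
        model = r0 / np.sqrt(1.0 + (2e-3 * np.pi * f * tau_ms) ** 2)
        return float(np.sum((model - y) ** 2))

    # lower bound 0.05 ms: flat (mean-driven) responses clamp to a fast but
    # finite kernel instead of a zero timescale
    res = minimize_scalar(sse, bounds=(0.05, 1e3), method="bounded",
                          options={"xatol": 1e-4})
    tau = float(res.x)
    if not np.isfinite(tau):
        return tau_fallback, False
    return tau, True


def response_timescale(neuron: NeuronParams, mu: float, sigma: float) -> float:
    """Timescale tau (ms) of the exponential linear-response kernel."""
    rate, _ = stationary_rate_and_voltage(neuron, mu, sigma)
    if rate < RATE_FLOOR:
        warnings.warn("vanishing rate: timescale fit degenerate, "
                      "falling back to the membrane time constant")
        return neuron.tau_m
    amp = rate_response_amplitude(neuron, mu, sigma)
    tau, ok = _fit_lorentzian_tau(TAU_FIT_FREQS, amp, neuron.tau_m)
    if not ok:
        warnings.warn("degenerate timescale fit, using membrane time constant")
    return tau


def _check_eif(neuron: NeuronParams) -> None:
    if neuron.a != 0 or neuron.b != 0:
        raise ValueError("transfer tables are defined for the EIF neuron "
                         "(a = b = 0); use neuron.without_adaptation()")


@dataclass
class TransferTable:
    """Precomputed Phi, Vmean and tau grids with bilinear lookup."""

    grid: GridSpec
    Phi: np.ndarray     # kHz, shape (n_mu, n_sigma)
    Vmean: np.ndarray   # mV
    tau: np.ndarray     # ms
    neuron_hash: str = ""
    clamp_warned: bool = field(default=False, repr=False)

    def __post_init__(self):
        shape = (len(self.grid.mu_values), len(self.grid.sigma_values))
        for name in ("Phi", "Vmean", "tau"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} grid shape {arr.shape} != {shape}")

    def lookup(self, mu: float, sigma: float) -> Tuple[float, float, float]:
        """Bilinear interpolation; out-of-range queries clamp to the border."""
        if self.Phi.size == 0:
            raise RuntimeError("empty transfer table")
        mu_c, sig_c = self._clamp(mu, sigma)
        vals = [
            float(_bilinear(self.grid.mu_values, self.grid.sigma_values,
                            tab, mu_c, sig_c))
            for tab in (self.Phi, self.Vmean, self.tau)
        ]
        return tuple(vals)  # type: ignore[return-value]

    def _clamp(self, mu, sigma):
        mg, sg = self.grid.mu_values, self.grid.sigma_values
        mu_c = min(max(mu, mg[0]), mg[-1])
        sig_c = min(max(sigma, sg[0]), sg[-1])
        if (mu_c != mu or sig_c != sigma) and not self.clamp_warned:
            logger.warning("transfer-table query (%g, %g) outside grid; "
                           "clamped to boundary", mu, sigma)
            self.clamp_warned = True
        return mu_c, sig_c

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        meta = json.dumps({"neuron_hash": self.neuron_hash,
                           "V_lb": V_LB, "dV": DV})
        np.savez(path, mu=self.grid.mu_values, sigma=self.grid.sigma_values,
                 Phi=self.Phi, Vmean=self.Vmean, tau=self.tau,
                 meta=np.array(meta))

    @classmethod
    def load(cls, path) -> "TransferTable":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            return cls(GridSpec(data["mu"], data["sigma"]), data["Phi"],
                       data["Vmean"], data["tau"],
                       neuron_hash=meta.get("neuron_hash", ""))

    def to_frames(self):
        """CSV-ready long-format DataFrame of all three grids."""
        import pandas as pd

        mu, sig = np.meshgrid(self.grid.mu_values, self.grid.sigma_values,
                              indexing="ij")
        return pd.DataFrame({
            "mu": mu.ravel(), "sigma": sig.ravel(),
            "rate_Hz": self.Phi.ravel() * 1e3,
            "Vmean_mV": self.Vmean.ravel(), "tau_ms": self.tau.ravel(),
        })


@njit(cache=True)
def _bilinear(xg, yg, table, x, y):
    ix = np.searchsorted(xg, x) - 1
    if ix < 0:
        ix = 0
    if ix > xg.shape[0] - 2:
        ix = xg.shape[0] - 2
    iy = np.searchsorted(yg, y) - 1
    if iy < 0:
        iy = 0
    if iy > yg.shape[0] - 2:
        iy = yg.shape[0] - 2
    fx = (x - xg[ix]) / (xg[ix + 1] - xg[ix])
    fy = (y - yg[iy]) / (yg[iy + 1] - yg[iy])
    return ((1 - fx) * (1 - fy) * table[ix, iy]
            + fx * (1 - fy) * table[ix + 1, iy]
            + (1 - fx) * fy * table[ix, iy + 1]
            + fx * fy * table[ix + 1, iy + 1])


def build_tables(neuron: NeuronParams, grid: GridSpec | None = None) -> TransferTable:
    """Fill the Phi, Vmean and tau grids for an EIF neuron.

    Deterministic: rebuilding with identical inputs yields bit-identical
    tables.  Nodes whose stationary rate vanishes get tau = tau_m (their
    dynamics are leak-dominated and the response fit is degenerate there).
    """
    neuron = neuron.without_adaptation()
    grid = grid or GridSpec.default()
    n_mu, n_sig = len(grid.mu_values), len(grid.sigma_values)
    Phi = np.zeros((n_mu, n_sig))
    Vmean = np.zeros((n_mu, n_sig))
    tau = np.zeros((n_mu, n_sig))
    omegas = 2e-3 * np.pi * TAU_FIT_FREQS[1:]
    failed = []
    for isig, sigma in enumerate(grid.sigma_values):
        rates, vmeans, p0 = _stationary_kernel(
            grid.mu_values, float(sigma), neuron.E_L, neuron.tau_m,
            neuron.Delta_T, neuron.V_T, neuron.V_r, neuron.T_ref, neuron.V_s)
        resp = _response_kernel(grid.mu_values, float(sigma), rates, p0,
                                omegas, neuron.E_L, neuron.tau_m,
                                neuron.Delta_T, neuron.V_T, neuron.V_r,
                                neuron.T_ref)
        gain0 = _static_gain(neuron, grid.mu_values, float(sigma))
        Phi[:, isig] = rates
        Vmean[:, isig] = vmeans
        for imu in range(n_mu):
            if not (np.isfinite(rates[imu]) and np.isfinite(vmeans[imu])):
                failed.append((float(grid.mu_values[imu]), float(sigma)))
                continue
            if rates[imu] < RATE_FLOOR:
                tau[imu, isig] = neuron.tau_m
            else:
                amp = np.concatenate([[gain0[imu]], np.abs(resp[imu])])
                tau[imu, isig], _ = _fit_lorentzian_tau(
                    TAU_FIT_FREQS, amp, neuron.tau_m)
    if failed:
        raise FloatingPointError(f"threshold integration failed at nodes: {failed[:10]}")
    return TransferTable(grid, Phi, Vmean, tau, neuron_hash=params_hash(neuron))


# ---------------------------------------------------------------------------
# cached default table


def _cache_dir() -> Path | None:
    d = Path.home() / ".cache" / "adexfield"
    try:
        d.mkdir(parents=True, exist_ok=True)
    except OSError:
        return None
    return d


def default_table(neuron: NeuronParams | None = None,
                  grid: GridSpec | None = None,
                  cache: bool = True) -> TransferTable:
    """Build (or load from the on-disk cache) the transfer table for a neuron.

    The cache key is the hash of the EIF parameters together with the grid,
    so changing either triggers a rebuild.
    """
    neuron = (neuron or NeuronParams()).without_adaptation()
    grid = grid or GridSpec.default()
    cache_dir = _cache_dir() if cache else None
    path = None
    if cache_dir is not None:
        key = params_hash(neuron) + "-" + _grid_hash(grid)
        path = cache_dir / f"table-{key}.npz"
        if path.exists():
            try:
                return TransferTable.load(path)
            except Exception:  # corrupted cache: rebuild
                path.unlink(missing_ok=True)
    table = build_tables(neuron, grid)
    if path is not None:
        try:
            table.save(path)
        except OSError:
            logger.warning("could not write transfer-table cache at %s", path)
    return table


def _grid_hash(grid: GridSpec) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(grid.mu_values.tobytes())
    h.update(grid.sigma_values.tobytes())
    return h.hexdigest()[:12]
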