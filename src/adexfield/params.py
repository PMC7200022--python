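"""Model parameters for the cortical E-I mass model and its spiking counterpart.

All quantities use a consistent ms/mV/pA/nS/pF unit system: currents divided
by the membrane capacitance are expressed in mV/ms (1 mV/ms corresponds to
0.2 nA at C = 200 pF), rates are kept in kHz internally, and the white-noise
amplitude ``sigma_ext`` carries units of mV*ms^(-1/2) so that its square is a
diffusion coefficient in mV^2/ms.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, Tuple

import yaml

PROJECTIONS = ("EE", "IE", "EI", "II")


@dataclass(frozen=True)
class NeuronParams:
    """Biophysical constants of a single AdEx neuron.

    The exponential term with slope ``Delta_T`` produces the spike upstroke;
    integration is cut off at ``V_s`` and the voltage reset to ``V_r``.
    Adaptation has a subthreshold conductance ``a`` and a spike-triggered
    increment ``b``; setting both to zero recovers the EIF neuron.
    """

    C: float = 200.0        # membrane capacitance, pF
    g_L: float = 10.0       # leak conductance, nS
    E_L: float = -65.0      # leak reversal, mV
    Delta_T: float = 1.5    # spike slope factor, mV
    V_T: float = -50.0      # exponential threshold, mV
    V_s: float = -40.0      # spike cutoff, mV
    V_r: float = -70.0      # reset, mV
    T_ref: float = 1.5      # refractory period, ms
    a: float = 15.0         # subthreshold adaptation, nS
    b: float = 40.0         # spike-triggered adaptation, pA
    E_A: float = -80.0      # adaptation reversal, mV
    tau_A: float = 200.0    # adaptation time constant, ms

    def __post_init__(self) -> None:
        if self.C <= 0 or self.g_L <= 0 or self.Delta_T <= 0:
            raise ValueError("C, g_L and Delta_T must be positive")
        if self.V_r >= self.V_s:
            raise ValueError("reset voltage must lie below the spike cutoff")
        if self.T_ref < 0 or self.tau_A <= 0:
            raise ValueError("T_ref must be >= 0 and tau_A > 0")
        if self.a < 0 or self.b < 0:
            raise ValueError("adaptation parameters must be non-negative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C/g_L in ms."""
        return self.C / self.g_L

    def without_adaptation(self) -> "NeuronParams":
        """EIF variant of this neuron (a = b = 0)."""
        return replace(self, a=0.0, b=0.0)


@dataclass(frozen=True)
class NetworkParams:
    """Coupling constants of the delay-coupled two-population network.

    ``J_xy`` is the maximal synaptic current (in mV/ms, i.e. divided by C)
    from population y onto x when every synapse is active; ``c_xy`` is the
    postsynaptic-current amplitude of a single spike arriving at a fully
    recovered synapse.  In-degrees ``K_E``/``K_I`` count excitatory and
    inhibitory afferents per neuron irrespective of the target population.
    """

    N_E: int = 10000
    N_I: int = 10000
    K_E: int = 800
    K_I: int = 200
    J_EE: float = 2.4
    J_IE: float = 2.6
    J_EI: float = -3.3
    J_II: float = -1.6
    c_EE: float = 0.3
    c_IE: float = 0.3
    c_EI: float = 0.5
    c_II: float = 0.5
    tau_s_E: float = 2.0    # excitatory synaptic time constant, ms
    tau_s_I: float = 5.0    # inhibitory synaptic time constant, ms
    d_E: float = 4.0        # delay onto excitatory neurons, ms
    d_I: float = 2.0        # delay onto inhibitory neurons, ms
    mu_ext_E: float = 0.0   # mean external drive to E, mV/ms
    mu_ext_I: float = 0.0   # mean external drive to I, mV/ms
    sigma_ext: float = 1.5  # external white-noise amplitude, mV*ms^(-1/2)

    def __post_init__(self) -> None:
        if self.J_EE <= 0 or self.J_IE <= 0:
            raise ValueError("excitatory couplings J_EE, J_IE must be positive")
        if self.J_EI >= 0 or self.J_II >= 0:
            raise ValueError("inhibitory couplings J_EI, J_II must be negative")
        for proj in PROJECTIONS:
            if self.c(proj) / abs(self.J(proj)) >= 1.0:
                raise ValueError(f"c_{proj}/|J_{proj}| must be < 1")
        if self.d_E < 0 or self.d_I < 0:
            raise ValueError("delays must be non-negative")
        if self.sigma_ext < 0:
            raise ValueError("sigma_ext must be non-negative")

    def J(self, proj: str) -> float:
        return getattr(self, f"J_{proj}")

    def c(self, proj: str) -> float:
        return getattr(self, f"c_{proj}")

    def K_pre(self, proj: str) -> int:
        """In-degree of the projection: K_E for excitatory afferents (xE),
        K_I for inhibitory afferents (xI)."""
        return self.K_E if proj[1] == "E" else self.K_I

    def tau_s(self, proj: str) -> float:
        return self.tau_s_E if proj[1] == "E" else self.tau_s_I

    def delay(self, proj: str) -> float:
        """Transmission delay of the projection; set by the target population."""
        return self.d_E if proj[0] == "E" else self.d_I

    def with_drive(self, mu_ext_E: float, mu_ext_I: float) -> "NetworkParams":
        return replace(self, mu_ext_E=mu_ext_E, mu_ext_I=mu_ext_I)


@dataclass(frozen=True)
class BallStickParams:
    """Morphology of the ball-and-stick neuron used for field coupling.

    A spherical soma (diameter ``d_s``) attached to a passive dendritic cable
    of length ``l_d`` and diameter ``d_d``, aligned with a uniform
    extracellular field.  Values are stored in the mixed units they are
    usually quoted in and converted to SI inside the cable formulas.
    """

    d_s: float = 10.0      # soma diameter, um
    C_m: float = 10.0      # specific membrane capacitance, mF/m^2
    rho_s: float = 2.8     # soma membrane resistivity, Ohm m^2
    l_d: float = 1200.0    # dendrite length, um
    d_d: float = 2.0       # dendrite diameter, um
    rho_m: float = 2.8     # dendrite membrane resistivity, Ohm m^2
    rho_a: float = 1.5     # axial resistivity, Ohm m

    def __post_init__(self) -> None:
        if any(v <= 0 for v in asdict(self).values()):
            raise ValueError("all ball-and-stick parameters must be positive")


#: Operating points of the bifurcation diagrams.  Values are the external
#: mean input currents C*mu_ext in nA for (E, I); the mean-field model and the
#: AdEx network use slightly different drives to reach the corresponding state.
OPERATING_POINTS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "A1": {"meanfield": (0.24, 0.24), "network": (0.22, 0.12), "state": "down"},
    "A2": {"meanfield": (0.26, 0.10), "network": (0.32, 0.30), "state": "LC_EI"},
    "A3": {"meanfield": (0.41, 0.34), "network": (0.40, 0.24), "state": "bi"},
    "B3": {"meanfield": (0.80, 0.36), "network": (0.76, 0.24), "state": "LC_aE"},
    "B4": {"meanfield": (0.76, 0.40), "network": (0.68, 0.24), "state": "down"},
}

#: Points A1-A3 are probed without adaptation, B3-B4 with the default (a, b).
POINT_ADAPTATION: Dict[str, bool] = {
    "A1": False, "A2": False, "A3": False, "B3": True, "B4": True,
}


def drive_from_nA(current_nA: float, neuron: NeuronParams) -> float:
    """Convert an input current C*mu in nA to a drive mu in mV/ms."""
    return current_nA * 1e3 / neuron.C


def operating_point_drive(point: str, backend: str,
                          neuron: NeuronParams | None = None) -> Tuple[float, float]:
    """Return (mu_ext_E, mu_ext_I) in mV/ms for a named operating point."""
    neuron = neuron or NeuronParams()
    try:
        nA_E, nA_I = OPERATING_POINTS[point][backend]
    except KeyError as exc:
        raise KeyError(f"unknown operating point or backend: {exc}") from exc
    return drive_from_nA(nA_E, neuron), drive_from_nA(nA_I, neuron)


# ---------------------------------------------------------------------------
# configuration files


_NEURON_KEYS = {
    "C": "C", "gL": "g_L", "EL": "E_L", "DeltaT": "Delta_T", "VT": "V_T",
    "Vs": "V_s", "Vr": "V_r", "Tref": "T_ref", "a": "a", "b": "b",
    "EA": "E_A", "tauA": "tau_A",
}
_NETWORK_KEYS = {
    "NE": "N_E", "NI": "N_I", "Ke": "K_E", "Ki": "K_I",
    "JEE": "J_EE", "JIE": "J_IE", "JEI": "J_EI", "JII": "J_II",
    "cEE": "c_EE", "cIE": "c_IE", "cEI": "c_EI", "cII": "c_II",
    "tausE": "tau_s_E", "tausI": "tau_s_I", "dE": "d_E", "dI": "d_I",
    "muextE": "mu_ext_E", "muextI": "mu_ext_I", "sigmaext": "sigma_ext",
}


def to_config(neuron: NeuronParams, net: NetworkParams) -> Dict[str, float]:
    """Flatten parameters into the short-name key scheme used in config files."""
    cfg: Dict[str, float] = {}
    for key, attr in _NEURON_KEYS.items():
        cfg[key] = getattr(neuron, attr)
    for key, attr in _NETWORK_KEYS.items():
        cfg[key] = getattr(net, attr)
    return cfg


def from_config(cfg: Dict[str, float]) -> Tuple[NeuronParams, NetworkParams]:
    """Build parameter objects from a flat config dict; unknown keys reject."""
    known = set(_NEURON_KEYS) | set(_NETWORK_KEYS)
    unknown = set(cfg) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    nkw = {attr: cfg[key] for key, attr in _NEURON_KEYS.items() if key in cfg}
    wkw = {attr: cfg[key] for key, attr in _NETWORK_KEYS.items() if key in cfg}
    for intkey in ("N_E", "N_I", "K_E", "K_I"):
        if intkey in wkw:
            wkw[intkey] = int(wkw[intkey])
    return NeuronParams(**nkw), NetworkParams(**wkw)


def save_config(path, neuron: NeuronParams, net: NetworkParams) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_config(neuron, net), fh, sort_keys=True)


def load_config(path) -> Tuple[NeuronParams, NetworkParams]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return from_config(cfg)


def params_hash(*objs) -> str:
    """Stable short hash of one or more parameter dataclasses."""
    payload = json.dumps([asdict(o) for o in objs], sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
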