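"""Conversion between extracellular electric fields and equivalent currents.

A uniform extracellular field polarizes the soma of a spatially extended
ball-and-stick neuron; the same somatic polarization can be produced in a
point EIF neuron by injecting a current through its (linearized) impedance.
The equivalent current amplitude for a field of amplitude A (V/m) at
frequency f is

    I_ext = A * |U_BS(f) / z_EIF(f)|,

where U_BS is the frequency-dependent polarization transfer function of the
ball-and-stick cable (somatic mV per V/m, i.e. an effective length) and
z_EIF the subthreshold impedance of the EIF neuron.  All cable quantities
are resolved to SI internally.

The conversion assumes no adaptation; with a, b > 0 the linearization around
the resting potential breaks down for slow inputs, so adaptive neurons are
converted with their EIF (a = b = 0) impedance and a warning is emitted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import BallStickParams, NeuronParams

__all__ = [
    "cable_constants",
    "bs_polarization_transfer",
    "eif_impedance",
    "current_from_field",
    "field_from_current",
    "conversion_curve",
    "FieldConversionCurve",
]


def cable_constants(bs: BallStickParams) -> dict:
    """Derived SI constants of the ball-and-stick morphology.

    Returns per-length dendritic membrane conductance ``g_m`` (S/m) and
    capacitance ``c_m`` (F/m), the axial conductance-length product ``g_a``
    (S m), and the lumped soma conductance ``g_s`` (S) and capacitance
    ``c_s`` (F).
    """
    d_d = bs.d_d * 1e-6
    d_s = bs.d_s * 1e-6
    C_m = bs.C_m * 1e-3  # mF/m^2 -> F/m^2
    return {
        "g_m": np.pi * d_d / bs.rho_m,
        "g_a": np.pi * (d_d / 2.0) ** 2 / bs.rho_a,
        "c_m": C_m * d_d * np.pi,
        "g_s": np.pi * d_s ** 2 / bs.rho_s,
        "c_s": C_m * np.pi * d_s ** 2,
    }


def bs_polarization_transfer(bs: BallStickParams, f: float | np.ndarray) -> np.ndarray:
    """Complex somatic polarization per unit field, in mV per V/m.

    Evaluates the cable solution for a uniform field aligned with the
    dendrite.  At f = 0 all omega-terms vanish analytically (static limit).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    k = cable_constants(bs)
    w = 2.0 * np.pi * f
    root = np.sqrt(k["g_m"] ** 2 + w ** 2 * k["c_m"] ** 2)
    alpha = np.sqrt((k["g_m"] + root) / (2.0 * k["g_a"]))
    beta = np.sqrt((-k["g_m"] + root) / (2.0 * k["g_a"]))
    z = alpha + 1j * beta  # complex propagation constant, 1/m
    l_d = bs.l_d * 1e-6
    gamma = 1.0 + np.exp(-2.0 * l_d * z)
    delta = gamma * (k["c_s"] * w * 1j + k["g_s"]) + z * k["g_a"] * (2.0 - gamma)
    u_m = k["g_a"] * (2.0 * np.exp(-z * l_d) - gamma) / delta  # meters
    return u_m * 1e3  # V per (V/m) -> mV per (V/m)


def eif_impedance(neuron: NeuronParams, f: float | np.ndarray) -> np.ndarray:
    """Complex subthreshold impedance of the EIF neuron in MOhm.

    The exponential term linearized at the reset contributes the factor
    (1 - exp((V_r - V_T)/Delta_T)), which is negligible for the default
    parameters; the impedance is then an RC low-pass 1/(g_L + i w C).
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("frequency must be non-negative")
    g_L = neuron.g_L * 1e-9  # S
    C = neuron.C * 1e-12     # F
    denom = g_L * (1.0 - np.exp((neuron.V_r - neuron.V_T) / neuron.Delta_T)) \
        + 2j * np.pi * C * f
    return 1.0 / denom / 1e6  # Ohm -> MOhm


def _ratio_pA_per_Vm(bs: BallStickParams, neuron: NeuronParams,
                     f: float | np.ndarray) -> np.ndarray:
    """|U_BS/z_EIF| in pA per (V/m)."""
    if neuron.a > 0 or neuron.b > 0:
        warnings.warn(
            "field conversion is defined for the non-adapting neuron; "
            "using the EIF (a=b=0) impedance", stacklevel=3)
        neuron = neuron.without_adaptation()
    u = bs_polarization_transfer(bs, f) * 1e-3   # V per (V/m)
    z = eif_impedance(neuron, f) * 1e6           # Ohm
    return np.abs(u / z) * 1e12                  # A -> pA


def current_from_field(A: float, f: float = 0.0,
                       bs: BallStickParams | None = None,
                       neuron: NeuronParams | None = None) -> float:
    """Equivalent input-current amplitude (pA) for a field of A V/m at f Hz."""
    if A < 0:
        raise ValueError("field amplitude must be non-negative")
    bs = bs or BallStickParams()
    neuron = neuron or NeuronParams().without_adaptation()
    return float(A * _ratio_pA_per_Vm(bs, neuron, f))


def field_from_current(I: float, f: float = 0.0,
                       bs: BallStickParams | None = None,
                       neuron: NeuronParams | None = None) -> float:
    """Field amplitude (V/m) whose equivalent current is I pA; exact inverse
    of :func:`current_from_field`."""
    if I < 0:
        raise ValueError("current amplitude must be non-negative")
    bs = bs or BallStickParams()
    neuron = neuron or NeuronParams().without_adaptation()
    return float(I / _ratio_pA_per_Vm(bs, neuron, f))


@dataclass
class FieldConversionCurve:
    """Current-per-field ratio as a function of frequency."""

    frequency_Hz: np.ndarray
    pA_per_Vm: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"frequency_Hz": self.frequency_Hz,
                             "pA_per_Vm": self.pA_per_Vm})


def conversion_curve(f_max: float = 100.0, n: int = 201,
                     bs: BallStickParams | None = None,
                     neuron: NeuronParams | None = None) -> FieldConversionCurve:
    """Tabulate the pA/(V/m) ratio over [0, f_max] Hz."""
    bs = bs or BallStickParams()
    neuron = neuron or NeuronParams().without_adaptation()
    f = np.linspace(0.0, f_max, n)
    return FieldConversionCurve(f, _ratio_pA_per_Vm(bs, neuron, f))
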