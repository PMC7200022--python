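"""External mean-current waveforms applied to the excitatory population.

Stimuli are defined as analytic functions of time and sampled exactly onto
the simulator grid, so endpoint values are preserved without interpolation.
Amplitudes are in pA; the simulators divide by the membrane capacitance to
obtain an additive drive in mV/ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List

import numpy as np


@dataclass
class StimulusWaveform:
    """A stimulus sampled on a uniform time grid (values in pA)."""

    dt: float
    values_pA: np.ndarray
    target: str = "E"

    def __post_init__(self) -> None:
        self.values_pA = np.asarray(self.values_pA, dtype=float)
        if not np.all(np.isfinite(self.values_pA)):
            raise ValueError("stimulus contains non-finite values")
        if self.target != "E":
            raise ValueError("only stimulation of the excitatory population is supported")

    @property
    def duration(self) -> float:
        return len(self.values_pA) * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.values_pA)) * self.dt


class Stimulus:
    """Analytic stimulus: a callable pA-valued function of time in ms."""

    def __call__(self, t: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def sample(self, duration: float, dt: float) -> StimulusWaveform:
        """Evaluate on the grid t_k = k*dt covering [0, duration)."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        t = np.arange(int(round(duration / dt))) * dt
        return StimulusWaveform(dt=dt, values_pA=np.asarray(self(t), dtype=float))

    def __add__(self, other: "Stimulus") -> "Stimulus":
        return CompositeStimulus([self, other])


@dataclass
class ZeroStimulus(Stimulus):
    def __call__(self, t):
        return np.zeros_like(np.asarray(t, dtype=float))


@dataclass
class CompositeStimulus(Stimulus):
    parts: List[Stimulus]

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return sum((p(t) for p in self.parts), np.zeros_like(t))


@dataclass
class DCStep(Stimulus):
    """Constant current of ``amplitude_pA`` on [onset, offset), zero outside."""

    amplitude_pA: float
    onset: float
    offset: float

    def __post_init__(self) -> None:
        if self.onset >= self.offset:
            raise ValueError("onset must precede offset")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.where((t >= self.onset) & (t < self.offset), self.amplitude_pA, 0.0)


@dataclass
class Sinusoid(Stimulus):
    """A*sin(2*pi*f*(t - onset)) for t >= onset, zero before."""

    amplitude_pA: float
    frequency_Hz: float
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency_Hz <= 0:
            raise ValueError("frequency must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        phase = 2e-3 * np.pi * self.frequency_Hz * (t - self.onset)
        return np.where(t >= self.onset, self.amplitude_pA * np.sin(phase), 0.0)


@dataclass
class DecayingKick(Stimulus):
    """Plateau followed by an exponential decay back to zero.

    Used to place the system gently inside a basin of attraction: the slow
    decay (tau much longer than membrane and synaptic timescales) avoids the
    transient over/undershoot a hard step would cause.
    """

    amplitude_pA: float
    onset: float = 0.0
    plateau: float = 500.0
    decay_tau: float = 500.0
    sign: int = 1

    def __post_init__(self) -> None:
        if self.decay_tau <= 0:
            raise ValueError("decay_tau must be positive")
        if self.sign not in (-1, 1):
            raise ValueError("sign must be +1 or -1")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        amp = self.sign * self.amplitude_pA
        t_end = self.onset + self.plateau
        out = np.zeros_like(t)
        out[(t >= self.onset) & (t < t_end)] = amp
        tail = t >= t_end
        out[tail] = amp * np.exp(-(t[tail] - t_end) / self.decay_tau)
        return out


def dc_step(amplitude_pA: float, onset: float, offset: float) -> DCStep:
    return DCStep(amplitude_pA, onset, offset)


def sinusoid(amplitude_pA: float, frequency_Hz: float, onset: float = 0.0) -> Sinusoid:
    return Sinusoid(amplitude_pA, frequency_Hz, onset)


def decaying_kick(amplitude_pA: float, plateau: float = 500.0,
                  decay_tau: float = 500.0, sign: int = 1,
                  onset: float = 0.0) -> DecayingKick:
    return DecayingKick(amplitude_pA, onset, plateau, decay_tau, sign)


def bistability_probe(amplitude_pA: float = 300.0, neg_onset: float = 500.0,
                      pos_onset: float = 4000.0, plateau: float = 500.0,
                      decay_tau: float = 500.0) -> CompositeStimulus:
    """The two-kick protocol: a negative kick into the low-rate state, a
    relaxation phase, then a positive kick toward the high-rate state."""
    return CompositeStimulus([
        DecayingKick(amplitude_pA, neg_onset, plateau, decay_tau, sign=-1),
        DecayingKick(amplitude_pA, pos_onset, plateau, decay_tau, sign=+1),
    ])
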