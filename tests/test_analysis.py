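"""Spectra, state classification, phase extraction and locking metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import adexfield as af
from adexfield.analysis import SpectrumResult
from adexfield.network import RateTrace


class TestWelchSpectrum:
    def test_pure_sinusoid_dominant_frequency(self):
        dt = 1.0
        t = np.arange(0, 5000.0, dt)
        x = 10.0 + 5.0 * np.sin(2e-3 * np.pi * 10.0 * t)
        spec = af.welch_spectrum(x, dt, 500.0)
        assert spec.dominant_frequency == pytest.approx(10.0, abs=0.5)

    def test_constant_trace_flagged(self):
        spec = af.welch_spectrum(np.full(10000, 3.0), 1.0, 500.0)
        assert np.isnan(spec.dominant_frequency)
        assert spec.dominant_power == 0.0
        assert not af.classify_oscillation(spec)

    def test_mixture_dominant_and_secondary_peak(self):
        dt = 1.0
        t = np.arange(0, 10000.0, dt)
        x = (2.0 * np.sin(2e-3 * np.pi * 10.0 * t)
             + 1.0 * np.sin(2e-3 * np.pi * 25.0 * t))  # 4:1 power ratio
        spec = af.welch_spectrum(x, dt, 1000.0)
        assert spec.dominant_frequency == pytest.approx(10.0, abs=0.5)
        sec = spec.power.copy()
        sec[np.abs(spec.frequency_Hz - 10.0) < 3.0] = 0.0
        f2 = spec.frequency_Hz[np.argmax(sec)]
        assert f2 == pytest.approx(25.0, abs=0.5)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            af.welch_spectrum(np.zeros(10), 1.0, 500.0)


class TestClassifyOscillation:
    def test_threshold_rules(self):
        f = np.linspace(0, 50, 51)
        strong = SpectrumResult(f, np.ones(51), 22.0, 50.0)
        slow = SpectrumResult(f, np.ones(51), 0.05, 50.0)
        weak = SpectrumResult(f, np.ones(51), 10.0, 0.5)
        assert af.classify_oscillation(strong)
        assert not af.classify_oscillation(slow)   # below 0.1 Hz floor
        assert not af.classify_oscillation(weak)   # below power density 1


def _synthetic_backend(rate_after_neg, rate_after_pos, dt=1.0):
    """Backend emitting constant rates before/after the positive kick."""
    def run(stimulus, duration):
        t = np.arange(0, duration, dt)
        r = np.where(t < 4000.0, rate_after_neg, rate_after_pos).astype(float)
        return RateTrace(t, r, "E")
    run.dt = dt
    return run


class TestBistabilityClassifier:
    def test_large_rate_difference_is_bistable(self):
        assert af.classify_bistability(_synthetic_backend(1.0, 30.0))

    def test_small_difference_is_not(self):
        assert not af.classify_bistability(_synthetic_backend(1.0, 6.0))

    def test_low_monostable_is_down(self):
        st_ = af.classify_state(_synthetic_backend(1.0, 1.0))
        assert st_.label == "down"

    def test_high_monostable_is_up(self):
        st_ = af.classify_state(_synthetic_backend(30.0, 30.0))
        assert st_.label == "up"


class TestInstantaneousPhase:
    def test_sinusoid_phase_slope(self):
        dt, f = 1.0, 8.0
        t = np.arange(0, 3000.0, dt)
        x = np.sin(2e-3 * np.pi * f * t)
        ph = af.instantaneous_phase(x, dt, smooth_sd_ms=5.0)
        valid = np.isfinite(ph)
        unwrapped = np.unwrap(ph[valid])
        slope = np.polyfit(t[valid], unwrapped, 1)[0]  # rad/ms
        assert slope == pytest.approx(2e-3 * np.pi * f, rel=0.02)

    def test_phase_zero_at_peak_and_pi_at_midpoint(self):
        dt = 0.5
        t = np.arange(0, 2000.0, dt)
        x = np.cos(2e-3 * np.pi * 10.0 * t)  # peaks at multiples of 100 ms
        ph = af.instantaneous_phase(x, dt, smooth_sd_ms=0.0)
        peak_idx = int(round(300.0 / dt))
        assert ph[peak_idx] == pytest.approx(0.0, abs=0.1)
        mid_idx = int(round(350.0 / dt))
        assert ph[mid_idx] == pytest.approx(np.pi, abs=0.1)

    def test_too_few_peaks_rejected(self):
        with pytest.raises(ValueError):
            af.instantaneous_phase(np.sin(np.linspace(0, 2 * np.pi, 100)),
                                   1.0)


class TestKuramoto:
    @pytest.mark.parametrize("phases,expected", [
        ((0.0, 0.0), 1.0),
        ((0.0, np.pi), 0.0),
        ((0.0, np.pi / 2), np.sqrt(2) / 2),
    ])
    def test_analytic_pairs(self, phases, expected):
        assert af.kuramoto_order(np.array(phases)) == pytest.approx(
            expected, abs=1e-12)

    def test_single_oscillator_rejected(self):
        with pytest.raises(ValueError):
            af.kuramoto_order(np.array([0.0]))

    @given(st.lists(st.floats(0, 2 * np.pi), min_size=2, max_size=8),
           st.floats(-10.0, 10.0))
    @settings(max_examples=200, deadline=None)
    def test_invariant_under_common_phase_shift(self, phases, shift):
        phases = np.array(phases)
        r0 = af.kuramoto_order(phases)
        r1 = af.kuramoto_order(phases + shift)
        assert r1 == pytest.approx(r0, abs=1e-9)
        assert -1e-12 <= r0 <= 1.0 + 1e-12


class TestPhaseLocking:
    def test_identical_sinusoids_have_near_zero_index(self):
        dt = 1.0
        t = np.arange(0, 10000.0, dt)
        x = np.sin(2e-3 * np.pi * 10.0 * t)
        res = af.phase_locking_index(RateTrace(t, 10 + 5 * x), 40 * x)
        assert res.locking_index < 0.02
        assert res.locked

    def test_detuned_sinusoids_beat(self):
        dt = 1.0
        t = np.arange(0, 20000.0, dt)
        x = np.sin(2e-3 * np.pi * 10.0 * t)
        y = np.sin(2e-3 * np.pi * 11.0 * t)
        res = af.phase_locking_index(RateTrace(t, 10 + 5 * x), 40 * y)
        assert res.locking_index > 0.1
        assert not res.locked


class TestEntrainment:
    def test_zero_amplitude_keeps_endogenous_frequency(self, eif, table):
        muE, muI = af.operating_point_drive("A2", "meanfield")
        net = af.NetworkParams(mu_ext_E=muE, mu_ext_I=muI)
        be = af.meanfield_backend(eif, net, table)
        res = af.entrainment_sweep(be, [18.0, 25.0, 30.0], 0.0)
        assert np.allclose(res.dominant_frequency,
                           res.dominant_frequency[0])

    def test_arnold_tongue_widens_with_amplitude(self, eif, table):
        """The 1:1 entrainment band is non-decreasing in stimulus
        amplitude (three-amplitude sweep around the endogenous frequency)."""
        muE, muI = af.operating_point_drive("A2", "meanfield")
        net = af.NetworkParams(mu_ext_E=muE, mu_ext_I=muI)
        be = af.meanfield_backend(eif, net, table)
        freqs = np.arange(16.0, 31.0, 1.0)
        widths = []
        for amp in (10.0, 20.0, 40.0):
            res = af.entrainment_sweep(be, freqs, amp)
            widths.append(res.entrained_mask().sum())
        assert widths[0] <= widths[1] <= widths[2]
        assert widths[2] > widths[0]


class TestScanStability:
    def test_labels_invariant_to_longer_protocol(self, eif, table):
        """Doubled relaxation windows must not change cell labels (a fixed
        point or limit cycle reached in the standard protocol stays put)."""
        net = af.NetworkParams()
        fac = af.meanfield_scan_factory(eif, net, table, dt=0.05)
        longer = af.ProbeProtocol(
            osc_window=(5000.0, 6000.0), mean1_window=(5000.0, 6000.0),
            pos_onset=6000.0, mean2_window=(9500.0, 10500.0),
            duration=10500.0)
        rng = np.random.default_rng(0)
        cells = list(zip(rng.uniform(0.0, 1.0, 10), rng.uniform(0.0, 0.5, 10)))
        for muE, muI in cells:
            short_label = af.classify_state(fac(muE, muI)).label
            long_label = af.classify_state(fac(muE, muI), longer).label
            assert short_label == long_label, (muE, muI)
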