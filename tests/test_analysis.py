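"""Waveform observables: peaks, spectra, synchronization, phase patterns."""

import io

import numpy as np
import pytest

from oscsense.analysis import (
    AnalysisError,
    PhasePattern,
    WaveformSet,
    circular_distance_deg,
    circular_median_deg,
    detect_peaks,
    dominant_frequency,
    is_synchronized,
    limit_cycle,
    phase_pattern,
)


def sine_set(freqs, phases_deg, fs=10e6, duration=2e-3, label=None):
    t = np.arange(int(duration * fs)) / fs
    channels = {
        str(i + 1): np.sin(2 * np.pi * (f * t - p / 360.0))
        for i, (f, p) in enumerate(zip(freqs, phases_deg))
    }
    return WaveformSet(time=t, channels=channels, label=label)


class TestWaveformSet:
    def test_rejects_nonuniform_grid(self):
        t = np.array([0.0, 1.0, 2.5, 3.0])
        with pytest.raises(ValueError, match="uniform"):
            WaveformSet(time=t, channels={"1": np.zeros(4)})

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            WaveformSet(time=np.arange(5.0), channels={"1": np.zeros(4)})

    def test_csv_round_trip(self):
        ws = sine_set([45e3, 45e3], [0, 90], duration=2e-4)
        buf = io.StringIO()
        ws.to_csv(buf)
        buf.seek(0)
        again = WaveformSet.from_csv(buf)
        assert again.channel_ids == ws.channel_ids
        np.testing.assert_allclose(again.time, ws.time)
        np.testing.assert_allclose(again.channels["2"], ws.channels["2"])

    def test_window_too_small_raises(self):
        ws = sine_set([45e3], [0], duration=1e-4)
        with pytest.raises(AnalysisError, match="empty window"):
            ws.window(1.0, 2.0)


class TestDetectPeaks:
    def test_sine_peak_spacing(self):
        period = 22e-6
        ws = sine_set([1 / period], [0], fs=10e6, duration=10 * period)
        peaks = detect_peaks(ws.channels["1"], ws.time)
        assert len(peaks) == 10
        np.testing.assert_allclose(np.diff(peaks), period, rtol=1e-3)

    def test_constant_channel_raises(self):
        t = np.arange(100) * 1e-6
        with pytest.raises(AnalysisError, match="no-peaks"):
            detect_peaks(np.ones(100), t)

    def test_relaxation_waveform_interval_matches_period(self, single_osc_config,
                                                         single_osc_waveform):
        from oscsense.oscillator import analytic_period

        T = analytic_period(single_osc_config.nodes[0], 10.0)
        peaks = detect_peaks(single_osc_waveform.channels["1"], single_osc_waveform.time)
        assert np.median(np.diff(peaks)) == pytest.approx(T, rel=5e-3)

    def test_min_distance_suppresses_spurious_peaks(self):
        period = 20e-6
        ws = sine_set([1 / period], [0], fs=5e6, duration=10 * period)
        noisy = ws.channels["1"] + 0.35 * np.sin(2 * np.pi * 7 / period * ws.time)
        loose = detect_peaks(noisy, ws.time, min_prominence=0.01)
        tight = detect_peaks(noisy, ws.time, min_prominence=0.01, min_distance=0.6 * period)
        assert len(tight) < len(loose)
        np.testing.assert_allclose(np.diff(tight), period, rtol=0.05)


class TestDominantFrequency:
    def test_pure_sine(self):
        ws = sine_set([45e3], [0], fs=10e6, duration=2e-3)
        assert dominant_frequency(ws.channels["1"], ws.time) == pytest.approx(45e3, rel=1e-4)

    def test_dominant_component_wins(self):
        ws = sine_set([45e3], [0], fs=10e6, duration=2e-3)
        mixed = ws.channels["1"] + 0.3 * np.sin(2 * np.pi * 90e3 * ws.time)
        assert dominant_frequency(mixed, ws.time) == pytest.approx(45e3, rel=1e-3)

    def test_dc_input_raises(self):
        t = np.arange(64) * 1e-6
        with pytest.raises(AnalysisError, match="degenerate-spectrum"):
            dominant_frequency(np.full(64, 2.5), t)

    def test_agrees_with_peak_intervals_on_oscillator(self, single_osc_waveform):
        f_fft = dominant_frequency(single_osc_waveform.channels["1"],
                                   single_osc_waveform.time)
        peaks = detect_peaks(single_osc_waveform.channels["1"], single_osc_waveform.time)
        f_peaks = 1.0 / np.median(np.diff(peaks))
        assert abs(f_fft - f_peaks) / f_peaks < 0.01


class TestIsSynchronized:
    def test_common_frequency_true(self):
        ws = sine_set([45e3, 45e3, 45e3], [0, 120, 240], duration=1e-3)
        assert is_synchronized(ws, transient_cut=1e-5)

    def test_distinct_frequencies_false(self):
        ws = sine_set([100e3, 150e3], [0, 0], duration=1e-3)
        assert not is_synchronized(ws, rel_tol=0.01, transient_cut=1e-5)


class TestPhasePattern:
    def test_half_period_offset_is_180(self):
        ws = sine_set([50e3, 50e3], [0, 180], duration=1e-3)
        pp = phase_pattern(ws, transient_cut=1e-5)
        assert pp.phase_deg["2"] == pytest.approx(180.0, abs=1.0)

    def test_identical_channel_is_zero(self):
        ws = sine_set([50e3, 50e3], [0, 0], duration=1e-3)
        pp = phase_pattern(ws, transient_cut=1e-5)
        assert circular_distance_deg(pp.phase_deg["2"], 0.0) < 1.0

    def test_time_shift_invariance(self):
        ws = sine_set([50e3, 50e3], [0, 236], duration=1e-3)
        shifted = WaveformSet(time=ws.time + 1.234e-3, channels=ws.channels)
        a = phase_pattern(ws, transient_cut=1e-5)
        b = phase_pattern(shifted, transient_cut=1e-5)
        assert circular_distance_deg(a.phase_deg["2"], b.phase_deg["2"]) < 0.5

    def test_voltage_scaling_invariance(self):
        ws = sine_set([50e3, 50e3], [0, 105], duration=1e-3)
        scaled = WaveformSet(
            time=ws.time, channels={k: 3.3 * v for k, v in ws.channels.items()}
        )
        a = phase_pattern(ws, transient_cut=1e-5)
        b = phase_pattern(scaled, transient_cut=1e-5)
        assert circular_distance_deg(a.phase_deg["2"], b.phase_deg["2"]) < 0.5

    def test_unsynchronized_raises(self):
        ws = sine_set([100e3, 150e3], [0, 0], duration=1e-3)
        with pytest.raises(AnalysisError, match="not-synchronized"):
            phase_pattern(ws, transient_cut=1e-5)

    def test_stable_across_disjoint_windows(self, antiphase_pair_waveform):
        """For a phase-locked pair the pattern agrees between disjoint
        post-transient analysis windows (well under 5 deg circular)."""
        ws = antiphase_pair_waveform
        w1 = ws.window(90e-6, 120e-6)
        w2 = ws.window(120e-6, 150e-6)
        p1 = phase_pattern(w1, transient_cut=1e-9)
        p2 = phase_pattern(w2, transient_cut=1e-9)
        assert circular_distance_deg(p1.phase_deg["2"], p2.phase_deg["2"]) < 5.0

    def test_measured_gesture_pattern_serialization_round_trip(self):
        """The hardware-measured pattern (0, 236, 105) deg survives JSON
        round-tripping exactly (representation check only)."""
        pp = PhasePattern(
            ref_channel="1", common_frequency=45e3,
            phase_deg={"1": 0.0, "2": 236.0, "3": 105.0}, synchronized=True,
        )
        again = PhasePattern.from_json(pp.to_json())
        assert again.phase_deg == pp.phase_deg
        assert again.common_frequency == 45e3

    def test_reference_phase_must_be_zero(self):
        with pytest.raises(ValueError):
            PhasePattern(ref_channel="1", common_frequency=1.0,
                         phase_deg={"1": 10.0, "2": 0.0}, synchronized=True)


class TestLimitCycle:
    def test_closed_loop_periodicity(self, antiphase_pair_waveform):
        """The post-transient trajectory closes on itself: points one period
        apart coincide to within a few percent of the voltage swing."""
        ws = antiphase_pair_waveform
        pp = phase_pattern(ws, transient_cut=90e-6)
        pts, proj = limit_cycle(ws, transient_cut=90e-6)
        period_samples = int(round(1.0 / pp.common_frequency / ws.dt))
        a = pts[:-period_samples]
        b = pts[period_samples:]
        swing = pts[:, 0].max() - pts[:, 0].min()
        assert np.median(np.abs(a - b)) < 0.05 * swing
        assert set(proj) == {"1-2"}

    def test_three_channel_projections(self, triple_waveform):
        pts, proj = limit_cycle(triple_waveform, transient_cut=100e-6)
        assert pts.shape[1] == 3
        assert set(proj) == {"1-2", "1-3", "2-3"}

    def test_transient_cut_beyond_record_raises(self, antiphase_pair_waveform):
        with pytest.raises(AnalysisError, match="empty-window"):
            limit_cycle(antiphase_pair_waveform, transient_cut=1.0)


class TestCircularStats:
    def test_median_avoids_wrap_bias(self):
        angles = np.array([358.0, 1.0, 3.0, 359.0, 2.0])
        med = circular_median_deg(angles)
        assert circular_distance_deg(med, 0.0) < 3.1

    def test_distance_symmetry_and_range(self):
        assert circular_distance_deg(10.0, 350.0) == pytest.approx(20.0)
        assert circular_distance_deg(350.0, 10.0) == pytest.approx(20.0)
        assert circular_distance_deg(0.0, 180.0) == pytest.approx(180.0)
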