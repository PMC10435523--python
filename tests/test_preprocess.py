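"""Resampling, band-pass denoising, windowing, beat splitting, quality."""

import numpy as np
import pytest

from piezobp import (
    FilterSpec,
    SegmentSpec,
    TimeSeries,
    VoltageSeries,
    assess_quality,
    bandpass,
    piezo_to_force,
    resample,
    segment,
    split_beats,
    synth_dual_piezo,
)
from piezobp.errors import ConfigurationError, DataError, NoBeatsDetected


@pytest.fixture(scope="module")
def pulse_window(subject):
    """20 s of band-passed pulse signal at the 1000 Hz working rate."""
    rec = synth_dual_piezo(subject, duration=20.0, fs_per_channel=2000.0)
    force = piezo_to_force(VoltageSeries(rec.ch1, rec.fs))
    return bandpass(resample(force, 1000.0))


class TestResample:
    def test_halving_rate_halves_length(self):
        s = TimeSeries(np.random.default_rng(0).normal(size=4000), 2000.0)
        out = resample(s, 1000.0)
        assert out.n == 2000 and out.fs == 1000.0

    def test_tone_amplitude_preserved(self):
        fs = 2000.0
        t = np.arange(int(4 * fs)) / fs
        s = TimeSeries(np.sin(2 * np.pi * 5 * t), fs)
        out = resample(s, 1000.0)
        assert np.ptp(out.values[500:-500]) == pytest.approx(2.0, rel=0.01)

    def test_identity_when_rate_unchanged(self):
        s = TimeSeries(np.arange(100.0), 500.0)
        assert resample(s, 500.0) is s

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            resample(TimeSeries(np.array([]), 100.0), 50.0)


class TestBandpass:
    def test_dc_rejected(self):
        s = TimeSeries(np.full(4000, 5.0), 1000.0)
        out = bandpass(s)
        assert np.max(np.abs(out.values[500:-500])) < 1e-6 * 5.0

    def test_in_band_tone_preserved(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        s = TimeSeries(np.sin(2 * np.pi * 1.5 * t), fs)
        out = bandpass(s)
        assert np.ptp(out.values[2000:-2000]) == pytest.approx(2.0, rel=0.05)

    def test_out_of_band_tone_attenuated(self):
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        s = TimeSeries(np.sin(2 * np.pi * 25 * t), fs)
        out = bandpass(s)
        assert np.ptp(out.values[2000:-2000]) < 0.1 * 2.0

    def test_idempotent_for_in_band_content(self):
        """Re-filtering changes an in-band composite by < 1% RMS (flat passband)."""
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        x = (
            np.sin(2 * np.pi * 1.5 * t)
            + 0.5 * np.sin(2 * np.pi * 3.0 * t)
            + 0.2 * np.sin(2 * np.pi * 5.0 * t)
        )
        once = bandpass(TimeSeries(x, fs))
        twice = bandpass(once).values
        core = slice(2000, -2000)
        err = twice[core] - once.values[core]
        assert np.sqrt(np.mean(err**2)) < 0.01 * np.std(once.values[core])

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            bandpass(TimeSeries(np.zeros(100), 10.0), FilterSpec())


class TestSegment:
    def test_default_spec_on_10500_samples_gives_9_windows(self):
        s = TimeSeries(np.zeros(10500), 1000.0)
        wins = segment(s)
        assert len(wins) == 9
        assert [int(round((w.t0) * 1000)) for w in wins] == list(range(0, 9001, 1050))

    def test_exact_fit_gives_one_window(self):
        assert len(segment(TimeSeries(np.zeros(1500), 1000.0))) == 1

    def test_zero_overlap_tiles(self):
        s = TimeSeries(np.zeros(4600), 1000.0)
        wins = segment(s, SegmentSpec(window=1500, overlap=0.0))
        assert len(wins) == 3

    def test_short_input_rejected(self):
        with pytest.raises(DataError):
            segment(TimeSeries(np.zeros(100), 1000.0))

    def test_windows_stay_in_bounds(self):
        s = TimeSeries(np.arange(5000.0), 1000.0)
        for w in segment(s):
            assert w.n == 1500
            assert w.values[0] == pytest.approx(w.t0 * 1000.0)


class TestSplitBeats:
    def test_ten_second_window_at_hr75_gives_11_to_13_beats(self, pulse_window):
        win = TimeSeries(pulse_window.values[:10000], 1000.0)
        beats = split_beats(win)
        assert 11 <= len(beats) <= 13

    def test_beats_are_normalized(self, pulse_window):
        for b in split_beats(TimeSeries(pulse_window.values[:10000], 1000.0)):
            assert b.values.min() == pytest.approx(0.0, abs=1e-12)
            assert b.values.max() == pytest.approx(1.0, abs=1e-12)
            assert b.amplitude > 0

    def test_flat_line_rejected(self):
        with pytest.raises(NoBeatsDetected):
            split_beats(TimeSeries(np.zeros(3000), 1000.0))

    def test_beat_duration_matches_heart_rate(self, pulse_window):
        beats = split_beats(TimeSeries(pulse_window.values[:10000], 1000.0))
        interior = [b for b in beats if 0 < b.start_index]
        assert np.median([b.duration for b in interior]) == pytest.approx(0.8, abs=0.02)


class TestAssessQuality:
    def test_clean_signal_is_ok(self, subject):
        rec = synth_dual_piezo(subject, duration=5.0, fs_per_channel=500.0)
        assert assess_quality(TimeSeries(rec.ch1, 500.0)).status == "ok"

    def test_pure_noise_is_no_signal(self):
        rng = np.random.default_rng(0)
        v = assess_quality(TimeSeries(rng.normal(0, 0.01, 2500), 500.0))
        assert v.status == "no_signal"

    def test_motion_burst_is_distorted(self, subject):
        rec = synth_dual_piezo(subject, duration=5.0, fs_per_channel=500.0)
        x = rec.ch1.copy()
        t = np.arange(x.size) / 500.0
        m = (t > 1.0) & (t < 3.5)  # half the window replaced by an artifact
        x[m] = 2 * np.ptp(rec.ch1) * np.exp(-(t[m] - 1) / 0.5) * np.sin(2 * np.pi * 7 * (t[m] - 1))
        assert assess_quality(TimeSeries(x, 500.0)).status == "distorted"

    def test_short_window_rejected(self):
        with pytest.raises(DataError):
            assess_quality(TimeSeries(np.zeros(100), 100.0))
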