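"""Fiducial detection, morphological features, heart rate, transit time, PWV."""

import numpy as np
import pytest

from piezobp import (
    SubjectRecord,
    TimeSeries,
    detect_fiducials,
    estimate_delta_t,
    heart_rate,
    local_pwv,
    morph_features,
    synth_dual_piezo,
)
from piezobp.errors import DataError, DegenerateBeat, IndeterminateDelay
from piezobp.fiducials import FiducialPoints, decimate_for_transmission
from piezobp.preprocess import BeatSegment


def _beat_from(values, fs=1000.0, raw_min=0.0, raw_max=1.0):
    return BeatSegment(np.asarray(values, float), fs, 0, raw_min, raw_max)


class TestDetectFiducials:
    def test_recovers_generator_truth_within_10ms(self, clean_beat):
        seg, beat = clean_beat
        fp = detect_fiducials(seg)
        for name, idx in (
            ("systolic_peak", fp.systolic_peak),
            ("dicrotic_notch", fp.dicrotic_notch),
            ("diastolic_peak", fp.diastolic_peak),
        ):
            assert abs(idx / seg.fs - beat.fiducials[name]) < 0.010

    def test_single_gaussian_is_degenerate(self):
        t = np.linspace(0, 1, 1000)
        x = np.exp(-(((t - 0.3) / 0.08) ** 2))
        with pytest.raises(DegenerateBeat):
            detect_fiducials(_beat_from(x / x.max()))

    def test_monotone_ramp_is_degenerate(self):
        with pytest.raises(DegenerateBeat):
            detect_fiducials(_beat_from(np.linspace(0, 1, 500)))

    def test_ordering_invariant_enforced(self):
        with pytest.raises(DegenerateBeat):
            FiducialPoints(foot=0, systolic_peak=50, dicrotic_notch=40, diastolic_peak=60)


class TestMorphFeatures:
    def test_symmetric_triangle_has_unit_area_ratio(self):
        x = np.concatenate([np.linspace(0, 1, 250), np.linspace(1, 0, 251)[1:]])
        fp = FiducialPoints(foot=0, systolic_peak=100, dicrotic_notch=250, diastolic_peak=350)
        mf = morph_features(_beat_from(x), fp)
        assert mf.area_ratio == pytest.approx(1.0, rel=0.02)

    def test_equal_heights_give_zero_augmentation(self, clean_beat):
        seg, _ = clean_beat
        fp = detect_fiducials(seg)
        flat = seg.values.copy()
        flat[fp.diastolic_peak] = flat[fp.systolic_peak]
        mf = morph_features(_beat_from(flat, raw_max=2.0), fp)
        assert mf.augmentation_index == pytest.approx(0.0, abs=1e-12)

    def test_st_matches_generator_truth(self, clean_beat):
        seg, beat = clean_beat
        fp = detect_fiducials(seg)
        mf = morph_features(seg, fp)
        assert abs(mf.st - beat.fiducials["dicrotic_notch"]) < 0.010

    def test_amplitude_scaling_invariance(self, clean_beat):
        """Scaling the raw waveform scales heights by k, leaves shape features."""
        seg, _ = clean_beat
        fp = detect_fiducials(seg)
        base = morph_features(seg, fp)
        k = 3.7
        scaled = BeatSegment(seg.values, seg.fs, 0, seg.raw_min * k, seg.raw_max * k)
        out = morph_features(scaled, fp)
        assert out.st == base.st and out.dt == base.dt
        assert out.augmentation_index == pytest.approx(base.augmentation_index)
        assert out.area_ratio == pytest.approx(base.area_ratio)
        assert out.systolic_height == pytest.approx(k * base.systolic_height)


class TestHeartRate:
    @pytest.mark.parametrize("period, expected", [(0.8, 75.0), (1.0, 60.0)])
    def test_from_uniform_periods(self, period, expected):
        fs = 1000.0
        beats = [_beat_from(np.zeros(int(period * fs) + 1), fs) for _ in range(4)]
        assert heart_rate(beats) == pytest.approx(expected, rel=1e-3)

    def test_median_robust_to_missed_beat(self):
        fs = 1000.0
        periods = [0.8, 0.8, 2.4]  # one missed beat -> doubled interval
        beats = [_beat_from(np.zeros(int(p * fs) + 1), fs) for p in periods]
        assert heart_rate(beats) == pytest.approx(75.0, rel=1e-3)

    def test_needs_two_beats(self):
        with pytest.raises(DataError):
            heart_rate([_beat_from(np.zeros(800))])


class TestDeltaT:
    def test_constructed_integer_shift(self):
        rng = np.random.default_rng(0)
        fs = 2000.0
        t = np.arange(int(10 * fs)) / fs
        ch1 = np.zeros(t.size)
        for k in range(1, 12):
            ch1 += np.exp(-(((t - 0.8 * k) / 0.02) ** 2))
        shift = 5
        ch2 = np.roll(ch1, shift)
        dt = estimate_delta_t(ch1, ch2, fs)
        assert dt == pytest.approx(shift / fs, abs=2e-5)

    @pytest.mark.parametrize("pwv", [2.0, 6.0, 12.0, 20.0])
    def test_simulator_truth_recovered_noise_free(self, pwv):
        s = SubjectRecord(0, 30, "male", 24, 120, 80, 72, pwv, 99)
        rec = synth_dual_piezo(s, duration=10.0, fs_per_channel=2000.0)
        dt = estimate_delta_t(rec.ch1, rec.ch2, rec.fs)
        assert dt == pytest.approx(rec.truth["delta_t"], abs=2.5e-4)

    def test_zero_delay_flagged(self, clean_recording):
        with pytest.raises(IndeterminateDelay):
            estimate_delta_t(clean_recording.ch1, clean_recording.ch1, clean_recording.fs)

    def test_monotone_in_pwv(self):
        """Faster waves give strictly shorter transit times."""
        delays = []
        for pwv in (2.0, 4.0, 8.0, 16.0):
            s = SubjectRecord(0, 30, "male", 24, 120, 80, 72, pwv, 5)
            rec = synth_dual_piezo(s, duration=8.0)
            delays.append(estimate_delta_t(rec.ch1, rec.ch2, rec.fs))
        assert all(a > b for a, b in zip(delays, delays[1:]))


class TestLocalPwv:
    @pytest.mark.parametrize(
        "dt, expected", [(7.5e-3, 2.0), (0.75e-3, 20.0)]
    )
    def test_range_endpoints(self, dt, expected):
        est = local_pwv(dt, 0.015)
        assert est.pwv == pytest.approx(expected)
        assert est.plausible

    def test_implausible_flagged(self):
        est = local_pwv(1e-4, 0.015)
        assert est.pwv == pytest.approx(150.0)
        assert not est.plausible

    def test_nonpositive_delay_rejected(self):
        with pytest.raises(DataError):
            local_pwv(0.0, 0.015)


class TestDecimation:
    def test_length_and_delay_passthrough(self):
        s = TimeSeries(np.random.default_rng(1).normal(size=20000), 2000.0)
        out, dt = decimate_for_transmission(s, delta_t=2.5e-3, out_fs=200.0)
        assert out.n == 2000
        assert dt == 2.5e-3  # bit-identical pass-through

    def test_upsampling_rejected(self):
        from piezobp.errors import ConfigurationError

        with pytest.raises(ConfigurationError):
            decimate_for_transmission(TimeSeries(np.zeros(100), 100.0), 1e-3, out_fs=200.0)

    def test_features_stable_across_rates(self, subject):
        """ST/DT from a 200 Hz waveform stay within 10 ms of the 1000 Hz values."""
        from piezobp import VoltageSeries, bandpass, piezo_to_force, resample, split_beats

        rec = synth_dual_piezo(subject, duration=10.0, fs_per_channel=2000.0)
        force = piezo_to_force(VoltageSeries(rec.ch1, rec.fs))
        results = {}
        for fs in (1000.0, 200.0):
            filt = bandpass(resample(force, fs))
            beats = split_beats(filt)
            mids = [b for b in beats if b.start_index > 0][1:-1]
            feats = [morph_features(b, detect_fiducials(b)) for b in mids]
            results[fs] = (
                float(np.median([f.st for f in feats])),
                float(np.median([f.dt for f in feats])),
            )
        assert abs(results[1000.0][0] - results[200.0][0]) < 0.010
        assert abs(results[1000.0][1] - results[200.0][1]) < 0.010
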