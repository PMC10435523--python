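"""Denoising, resampling, windowing and beat segmentation.

The converted pulse signal is resampled to a 1000 Hz working rate,
band-pass filtered (3rd-order Butterworth, 0.5-8 Hz, applied
forward-backward so fiducial timing is unbiased), cut into 1500-sample
windows with 30% overlap, and each window split into foot-to-foot beats
normalized to [0, 1].  A lightweight peak-count quality check classifies
raw windows as ok / distorted / no_signal for the pressure controller.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal

import numpy as np
from scipy import signal

from .errors import ConfigurationError, DataError, NoBeatsDetected
from .transduce import TimeSeries

__all__ = [
    "FilterSpec",
    "SegmentSpec",
    "QualityVerdict",
    "BeatSegment",
    "resample",
    "bandpass",
    "segment",
    "split_beats",
    "assess_quality",
]


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass denoising filter: 3rd-order IIR, 0.5-8 Hz by default."""

    order: int = 3
    low_hz: float = 0.5
    high_hz: float = 8.0
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ConfigurationError("need 0 < low < high cutoff")
        if self.order < 1:
            raise ConfigurationError("filter order must be >= 1")


@dataclass(frozen=True)
class SegmentSpec:
    """Windowing at the working rate: 1500 samples, 30% overlap, 1000 Hz."""

    window: int = 1500
    overlap: float = 0.30
    working_fs: float = 1000.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < 1:
            raise ConfigurationError("overlap must be in [0, 1)")
        if self.window < 2:
            raise ConfigurationError("window must be >= 2 samples")

    @property
    def hop(self) -> int:
        return int(round(self.window * (1.0 - self.overlap)))


@dataclass(frozen=True)
class QualityVerdict:
    status: Literal["ok", "distorted", "no_signal"]
    peak_count: int
    mean_interval_s: float | None


@dataclass(frozen=True)
class BeatSegment:
    """One foot-to-foot beat, min-max normalized to [0, 1].

    Pre-normalization amplitude information (raw min / max) is retained
    so physical peak heights can be reconstructed downstream.
    """

    values: np.ndarray  # normalized to [0, 1]
    fs: float
    start_index: int  # index of the foot within the parent window
    raw_min: float
    raw_max: float

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def amplitude(self) -> float:
        """Pre-normalization peak-to-peak amplitude."""
        return self.raw_max - self.raw_min


def resample(series: TimeSeries, target_fs: float) -> TimeSeries:
    """Band-limited polyphase resampling; duration preserved within one sample."""
    if target_fs <= 0:
        raise ConfigurationError(f"target_fs must be > 0, got {target_fs}")
    if series.n == 0:
        raise DataError("cannot resample an empty series")
    if target_fs == series.fs:
        return series
    ratio = Fraction(target_fs / series.fs).limit_denominator(10_000)
    out = signal.resample_poly(series.values, ratio.numerator, ratio.denominator)
    return TimeSeries(out, target_fs, series.t0)


def bandpass(series: TimeSeries, spec: FilterSpec | None = None) -> TimeSeries:
    """Apply the band-pass denoising filter (zero-phase by default)."""
    spec = spec or FilterSpec()
    if spec.high_hz >= series.fs / 2:
        raise ConfigurationError(
            f"high cutoff {spec.high_hz} Hz >= Nyquist {series.fs / 2} Hz"
        )
    sos = signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=series.fs, output="sos"
    )
    if spec.zero_phase:
        out = signal.sosfiltfilt(sos, series.values)
    else:
        out = signal.sosfilt(sos, series.values)
    return TimeSeries(out, series.fs, series.t0)


def segment(series: TimeSeries, spec: SegmentSpec | None = None) -> list[TimeSeries]:
    """Cut the series into full overlapping windows (half-open ranges).

    Window k covers samples [k*hop, k*hop + window); only complete
    windows are emitted.
    """
    spec = spec or SegmentSpec()
    x = series.values
    if x.size < spec.window:
        raise DataError(f"series ({x.size} samples) shorter than one window ({spec.window})")
    hop = spec.hop
    windows = []
    for start in range(0, x.size - spec.window + 1, hop):
        windows.append(
            TimeSeries(x[start : start + spec.window], series.fs, series.t0 + start / series.fs)
        )
    return windows


def _find_systolic_peaks(x: np.ndarray, fs: float, prominence_frac: float = 0.30) -> np.ndarray:
    """Candidate systolic peaks: prominent maxima at least 0.3 s apart.

    The prominence floor is a fraction of the robust amplitude span
    (1st-99th percentile), which tracks the dominant spikes of both
    pulse-shaped and piezo-spike-shaped signals.
    """
    span = float(np.subtract(*np.percentile(x, [99, 1])))
    prominence = prominence_frac * span
    if prominence <= 0:
        return np.array([], dtype=int)
    peaks, _ = signal.find_peaks(x, prominence=prominence, distance=max(int(0.3 * fs), 1))
    return peaks


def split_beats(window: TimeSeries) -> list[BeatSegment]:
    """Split a band-passed window into foot-to-foot normalized beats.

    Feet are the signal minima between consecutive systolic peaks (the
    trough preceding each maximal upslope).  Beats clipped by the window
    boundary are dropped.  Each beat is min-max normalized; the raw
    extrema are kept as metadata.
    """
    x = window.values
    peaks = _find_systolic_peaks(x, window.fs)
    if peaks.size < 1:
        raise NoBeatsDetected("no systolic peak in window")
    # Keep only the dominant (systolic) maxima: a prominent diastolic
    # peak sits well below the systolic prominence and must not split
    # the beat in two.
    prominences = signal.peak_prominences(x, peaks)[0]
    peaks = peaks[prominences >= 0.45 * prominences.max()]
    feet = [p0 + int(np.argmin(x[p0:p1])) for p0, p1 in zip(peaks[:-1], peaks[1:])]
    # The window usually starts and ends mid-beat.  A minimum before the
    # first peak (or after the last) is a genuine foot when it is interior,
    # or when it sits at foot level right on the boundary; a boundary
    # minimum well above foot level means the beat is clipped -> dropped.
    at_foot_level = lambda v: v <= float(x.min()) + 0.07 * float(np.ptp(x))
    if peaks[0] > 1:
        pre = int(np.argmin(x[: peaks[0]]))
        if pre > 0 or at_foot_level(x[pre]):
            feet = [pre] + feet
    if peaks[-1] < x.size - 2:
        post = peaks[-1] + int(np.argmin(x[peaks[-1] :]))
        if (post < x.size - 1 or at_foot_level(x[post])) and (not feet or post > feet[-1]):
            feet = feet + [post]
    feet = np.asarray(feet, dtype=int)
    if feet.size < 2:
        raise NoBeatsDetected("fewer than two pulse feet in window")
    beats = []
    for f0, f1 in zip(feet[:-1], feet[1:]):
        seg = x[f0 : f1 + 1]  # include the terminal foot sample
        lo, hi = float(seg.min()), float(seg.max())
        if hi <= lo:
            continue
        beats.append(
            BeatSegment(
                values=(seg - lo) / (hi - lo),
                fs=window.fs,
                start_index=int(f0),
                raw_min=lo,
                raw_max=hi,
            )
        )
    if not beats:
        raise NoBeatsDetected("no complete foot-to-foot beat in window")
    return beats


def _pulse_band_fraction(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Fraction of non-DC power inside the pulse band."""
    spec = np.abs(np.fft.rfft(x - np.mean(x))) ** 2
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    total = float(spec[1:].sum())
    if total == 0:
        return 0.0
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    return float(spec[in_band].sum()) / total


def assess_quality(
    raw_window: TimeSeries,
    min_interval_s: float = 0.3,
    max_interval_s: float = 2.0,
    max_interval_cv: float = 0.5,
    prominence_frac: float = 0.30,
    pulse_band_hz: tuple[float, float] = (0.5, 25.0),
    min_band_fraction: float = 0.5,
) -> QualityVerdict:
    """Classify a raw window for the closed-loop pressure controller.

    ok        : >= 2 prominent peaks, plausible and regular inter-peak
                intervals (CV below ``max_interval_cv``) and consistent
                peak amplitudes (prominence CV below the same bound).
    no_signal : fewer than 2 prominent peaks, or the signal's power is
                spread outside the pulse band (broadband noise only).
    distorted : peaks present but implausible rhythm, irregular
                intervals, or wildly varying peak amplitudes.

    The operational thresholds (prominence as a fraction of the window
    IQR, interval CV bound, pulse-band power fraction) are exposed as
    keyword arguments.
    """
    if raw_window.duration < 2.0:
        raise DataError("quality assessment needs at least a 2 s window")
    if _pulse_band_fraction(raw_window.values, raw_window.fs, pulse_band_hz) < min_band_fraction:
        return QualityVerdict("no_signal", 0, None)
    peaks = _find_systolic_peaks(raw_window.values, raw_window.fs, prominence_frac)
    if peaks.size < 2:
        return QualityVerdict("no_signal", int(peaks.size), None)
    intervals = np.diff(peaks) / raw_window.fs
    mean_iv = float(np.mean(intervals))
    interval_cv = float(np.std(intervals) / mean_iv) if mean_iv > 0 else np.inf
    prominences = signal.peak_prominences(raw_window.values, peaks)[0]
    mean_prom = float(np.mean(prominences))
    prom_cv = float(np.std(prominences) / mean_prom) if mean_prom > 0 else np.inf
    plausible = np.all((intervals >= min_interval_s) & (intervals <= max_interval_s))
    ok = plausible and interval_cv < max_interval_cv and prom_cv < max_interval_cv
    return QualityVerdict("ok" if ok else "distorted", int(peaks.size), mean_iv)
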