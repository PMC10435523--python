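"""Synthetic subjects, pulse waveforms and dual-site piezo recordings.

Everything downstream (transduction, preprocessing, fiducial detection,
delay/PWV estimation, BP regression, closed-loop control) is exercised
against signals generated here with known ground truth, so the whole
pipeline is testable with no hardware and no external data.

The generator emulates the measurement physics at the level the pipeline
sees it:

* A beat is the sum of three positive component waves — the forward
  ejection wave plus two peripheral reflections — with gradually
  attenuated amplitudes, giving the classic three-peak arterial pulse
  with a dicrotic notch between the second and third waves.
* The distal sensing site receives the same pulse train delayed by
  spacing / PWV and slightly damped (absorption along the artery).
* Each force waveform is pushed through the forward transducer model to
  yield the piezo voltage the ADC would sample: a strong positive spike
  on the systolic upstroke, a negative valley on the downstroke, and two
  weak peaks from the reflections.
* Cohort blood pressures follow the per-sex normal distributions of the
  study population; age, BMI, heart rate and PWV are drawn independently
  within their ranges.

No arterial fluid dynamics or vessel mechanics are modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import truncnorm

from .errors import ConfigurationError
from .transduce import ForceWaveform, TransduceParams, force_to_piezo

__all__ = [
    "CohortSpec",
    "SubjectRecord",
    "MorphologyParams",
    "NoiseSpec",
    "PiezoRecording",
    "SyntheticBeat",
    "sample_cohort",
    "synth_beat",
    "synth_dual_piezo",
    "synth_hgcp_trajectory",
]

#: Beat period (s) at which MorphologyParams widths are stated; widths are
#: rescaled proportionally for other heart rates so morphology is
#: HR-invariant in fraction-of-beat space.
REFERENCE_PERIOD_S = 0.8


@dataclass(frozen=True)
class CohortSpec:
    """Population parameters of the synthetic cohort.

    BP means/SDs are per sex, in mmHg; ranges are uniform-sampling bounds.
    Defaults reproduce the study population statistics: male SBP
    120.68 +/- 11.86, DBP 79.58 +/- 11.36; female SBP 108.27 +/- 12.06,
    DBP 74.75 +/- 8.12; ages 9-62; local PWV 2-20 m/s.
    """

    male_sbp: tuple[float, float] = (120.68, 11.86)
    male_dbp: tuple[float, float] = (79.58, 11.36)
    female_sbp: tuple[float, float] = (108.27, 12.06)
    female_dbp: tuple[float, float] = (74.75, 8.12)
    age_range: tuple[float, float] = (9.0, 62.0)
    bmi_range: tuple[float, float] = (17.0, 32.0)
    hr_range: tuple[float, float] = (55.0, 95.0)
    pwv_range: tuple[float, float] = (2.0, 20.0)
    #: minimum pulse pressure enforced when pairing SBP with DBP (mmHg)
    min_pulse_pressure: float = 10.0
    #: optional linear trend of SBP with age (mmHg/year), default off
    sbp_age_slope: float = 0.0

    def __post_init__(self) -> None:
        for name in ("male_sbp", "male_dbp", "female_sbp", "female_dbp"):
            mean, sd = getattr(self, name)
            if not sd > 0:
                raise ConfigurationError(f"{name} SD must be > 0, got {sd}")
        for sex in ("male", "female"):
            if getattr(self, f"{sex}_sbp")[0] <= getattr(self, f"{sex}_dbp")[0]:
                raise ConfigurationError(f"{sex} SBP mean must exceed DBP mean")
        lo, hi = self.pwv_range
        if not (0 < lo < hi <= 30):
            raise ConfigurationError("PWV range must lie within (0, 30] m/s")

    def bp_params(self, sex: str) -> tuple[tuple[float, float], tuple[float, float]]:
        if sex == "male":
            return self.male_sbp, self.male_dbp
        if sex == "female":
            return self.female_sbp, self.female_dbp
        raise ConfigurationError(f"unknown sex {sex!r}")


@dataclass(frozen=True)
class SubjectRecord:
    """One synthetic subject with their ground-truth physiology."""

    subject_id: int
    age: float
    sex: Literal["male", "female"]
    bmi: float
    sbp: float
    dbp: float
    hr: float
    pwv: float
    seed: int

    def __post_init__(self) -> None:
        if not self.sbp > self.dbp:
            raise ConfigurationError("SBP must exceed DBP")
        if not 30 <= self.hr <= 220:
            raise ConfigurationError(f"HR {self.hr} outside [30, 220] bpm")


@dataclass(frozen=True)
class MorphologyParams:
    """Shape parameters of the three-component-wave beat model.

    Component waves are asymmetric Gaussian bumps (rise sharper than
    fall).  Amplitudes are relative to the first (forward) wave and must
    decrease strictly; timing offsets are fractions of the beat period
    and must increase strictly; widths are fall-side standard deviations
    in seconds at the 0.8 s reference period.
    """

    amplitudes: tuple[float, float, float] = (1.0, 0.58, 0.30)
    offsets: tuple[float, float, float] = (0.13, 0.28, 0.58)
    widths_s: tuple[float, float, float] = (0.058, 0.075, 0.090)
    rise_fraction: float = 0.60
    distal_damping: float = 0.85

    def __post_init__(self) -> None:
        a = self.amplitudes
        if not (a[0] > a[1] > a[2] > 0):
            raise ConfigurationError("amplitudes must be strictly decreasing and positive")
        o = self.offsets
        if not (0 < o[0] < o[1] < o[2] < 1):
            raise ConfigurationError("offsets must increase strictly within (0, 1)")
        if not all(w > 0 for w in self.widths_s):
            raise ConfigurationError("widths must be positive")
        if not 0 < self.rise_fraction <= 1:
            raise ConfigurationError("rise_fraction must be in (0, 1]")
        if not 0 < self.distal_damping <= 1:
            raise ConfigurationError("distal damping must be in (0, 1]")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive disturbances on the simulated piezo voltage.

    white_sd is a fraction of the clean channel's peak-to-peak voltage;
    drift is a slow baseline sinusoid (respiration-like); motion
    artifacts are damped-sinusoid bursts at Poisson-distributed times.
    """

    white_sd: float = 0.0
    drift_amplitude: float = 0.0
    drift_hz: float = 0.25
    burst_rate_per_min: float = 0.0
    burst_amplitude: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.white_sd, self.drift_amplitude, self.drift_hz,
                self.burst_rate_per_min, self.burst_amplitude)
        if any(v < 0 for v in vals):
            raise ConfigurationError("noise parameters must be non-negative")


@dataclass(frozen=True)
class SyntheticBeat:
    """One synthesized beat with its analytic ground truth."""

    waveform: ForceWaveform  # mmHg scale: min == DBP, max == SBP
    period: float  # s
    fiducials: dict[str, float]  # foot / systolic_peak / dicrotic_notch / diastolic_peak, s


@dataclass(frozen=True)
class PiezoRecording:
    """Two synchronized piezo voltage channels plus acquisition metadata."""

    ch1: np.ndarray  # proximal voltage (V, a.u.)
    ch2: np.ndarray  # distal voltage
    fs: float  # per-channel sampling rate (Hz)
    spacing_m: float  # sensor separation
    subject: SubjectRecord
    seed: int
    truth: dict = field(default_factory=dict, compare=False)

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.ch1.size) / self.fs

    @property
    def duration(self) -> float:
        return self.ch1.size / self.fs


def sample_cohort(
    spec: CohortSpec,
    n: int,
    seed: int,
    sex: Literal["male", "female", None] = None,
) -> list[SubjectRecord]:
    """Draw ``n`` synthetic subjects with per-sex BP distributions.

    SBP is drawn from the sex-specific normal; DBP from its normal
    truncated above at SBP - min_pulse_pressure, so the SBP marginal
    matches the population mean/SD exactly while every subject keeps a
    physiologic pulse pressure.  Deterministic given ``seed``.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    if sex is None:
        sexes = np.where(rng.random(n) < 0.5, "male", "female")
    else:
        spec.bp_params(sex)  # validates the label
        sexes = np.full(n, sex, dtype=object)

    age = rng.uniform(*spec.age_range, n)
    bmi = rng.uniform(*spec.bmi_range, n)
    hr = rng.uniform(*spec.hr_range, n)
    pwv = rng.uniform(*spec.pwv_range, n)
    sbp = np.empty(n)
    dbp = np.empty(n)
    for label in ("male", "female"):
        mask = sexes == label
        if not mask.any():
            continue
        (s_mu, s_sd), (d_mu, d_sd) = spec.bp_params(label)
        m = int(mask.sum())
        s = rng.normal(s_mu, s_sd, m) + spec.sbp_age_slope * (age[mask] - np.mean(spec.age_range))
        upper = (s - spec.min_pulse_pressure - d_mu) / d_sd
        d = truncnorm.rvs(-np.inf, upper, loc=d_mu, scale=d_sd, random_state=rng)
        sbp[mask], dbp[mask] = s, d
    seeds = rng.integers(0, 2**31 - 1, n)
    return [
        SubjectRecord(
            subject_id=i,
            age=float(age[i]),
            sex=str(sexes[i]),
            bmi=float(bmi[i]),
            sbp=float(sbp[i]),
            dbp=float(dbp[i]),
            hr=float(hr[i]),
            pwv=float(pwv[i]),
            seed=int(seeds[i]),
        )
        for i in range(n)
    ]


def _component_wave(t: np.ndarray, center: float, width: float, rise_fraction: float) -> np.ndarray:
    """Asymmetric Gaussian bump: rise-side sigma = rise_fraction * fall-side."""
    sigma = np.where(t < center, rise_fraction * width, width)
    return np.exp(-((t - center) / sigma) ** 2)


def _beat_shape(t: np.ndarray, period: float, morph: MorphologyParams) -> np.ndarray:
    """Evaluate the unit-scale three-wave beat at times t (periodic)."""
    tau = np.mod(t, period)
    scale = period / REFERENCE_PERIOD_S
    out = np.zeros_like(tau, dtype=float)
    for amp, off, w in zip(morph.amplitudes, morph.offsets, morph.widths_s):
        out += amp * _component_wave(tau, off * period, w * scale, morph.rise_fraction)
    return out


def _beat_truth(period: float, morph: MorphologyParams, fs: float) -> dict[str, float]:
    """Analytic fiducial times found on a 10x oversampled grid."""
    n = max(int(round(10 * fs * period)), 1000)
    tt = np.arange(n) / (n / period)
    y = _beat_shape(tt, period, morph)
    maxima, _ = find_peaks(y)
    if maxima.size < 3:
        raise ConfigurationError("morphology does not produce three distinct peaks")
    m1, m2, m3 = maxima[:3]
    notch = m2 + int(np.argmin(y[m2:m3]))
    return {
        "foot": 0.0,
        "systolic_peak": float(tt[m1]),
        "dicrotic_notch": float(tt[notch]),
        "diastolic_peak": float(tt[m3]),
    }


def synth_beat(
    subject: SubjectRecord,
    morph: MorphologyParams | None = None,
    fs: float = 1000.0,
) -> SyntheticBeat:
    """Synthesize one beat on the mmHg scale with ground-truth fiducials.

    Duration is 60/HR seconds; the waveform minimum maps to the subject's
    DBP and the maximum to SBP.
    """
    morph = morph or MorphologyParams()
    if fs < 100:
        raise ConfigurationError(f"fs must be >= 100 Hz, got {fs}")
    period = 60.0 / subject.hr
    t = np.arange(int(round(period * fs))) / fs
    y = _beat_shape(t, period, morph)
    lo, hi = float(y.min()), float(y.max())
    bp = subject.dbp + (y - lo) * (subject.sbp - subject.dbp) / (hi - lo)
    return SyntheticBeat(
        waveform=ForceWaveform(bp, fs),
        period=period,
        fiducials=_beat_truth(period, morph, fs),
    )


def _apply_noise(
    v: np.ndarray, t: np.ndarray, noise: NoiseSpec, rng: np.random.Generator
) -> np.ndarray:
    ptp = float(np.ptp(v)) or 1.0
    out = v.copy()
    if noise.white_sd > 0:
        out += rng.normal(0.0, noise.white_sd * ptp, v.size)
    if noise.drift_amplitude > 0:
        phase = rng.uniform(0, 2 * math.pi)
        out += noise.drift_amplitude * ptp * np.sin(2 * math.pi * noise.drift_hz * t + phase)
    if noise.burst_rate_per_min > 0 and noise.burst_amplitude > 0:
        duration = t[-1] if t.size else 0.0
        n_events = rng.poisson(noise.burst_rate_per_min * duration / 60.0)
        for t0 in rng.uniform(0, duration, n_events):
            mask = t >= t0
            dt_local = t[mask] - t0
            out[mask] += (
                noise.burst_amplitude * ptp
                * np.exp(-dt_local / 0.15)
                * np.sin(2 * math.pi * 10.0 * dt_local)
            )
    return out


def synth_dual_piezo(
    subject: SubjectRecord,
    morph: MorphologyParams | None = None,
    noise: NoiseSpec | None = None,
    duration: float = 10.0,
    fs_per_channel: float = 2000.0,
    spacing: float = 0.015,
    transducer: TransduceParams | None = None,
    amplitude: float = 1.0,
) -> PiezoRecording:
    """Simulate a two-site piezo recording with full ground truth.

    The distal channel is the proximal pulse train delayed by
    spacing / PWV and damped by ``morph.distal_damping``; both force
    trains are forward-transduced to voltage and noise is added.  The
    voltage scale is arbitrary (controlled by ``amplitude``).
    """
    morph = morph or MorphologyParams()
    noise = noise or NoiseSpec()
    transducer = transducer or TransduceParams()
    if spacing <= 0:
        raise ConfigurationError(f"sensor spacing must be > 0, got {spacing}")
    period = 60.0 / subject.hr
    if duration < 2 * period:
        raise ConfigurationError("duration must cover at least 2 beats")
    delta_t = spacing / subject.pwv
    if delta_t >= period:
        raise ConfigurationError(
            f"inter-site delay {delta_t:.3g} s >= beat period {period:.3g} s is implausible"
        )
    n = int(round(duration * fs_per_channel))
    t = np.arange(n) / fs_per_channel
    pulse1 = _beat_shape(t, period, morph)
    pulse2 = morph.distal_damping * _beat_shape(t - delta_t, period, morph)
    rng = np.random.default_rng(subject.seed)
    channels = []
    for pulse in (pulse1, pulse2):
        force = ForceWaveform(amplitude * pulse, fs_per_channel)
        v = force_to_piezo(force, transducer).values
        channels.append(_apply_noise(v, t, noise, rng))

    beat = synth_beat(subject, morph, fs=fs_per_channel)
    truth = {
        "delta_t": delta_t,
        "pwv": subject.pwv,
        "period": period,
        "sbp": subject.sbp,
        "dbp": subject.dbp,
        "hr": subject.hr,
        "beat_fiducials": beat.fiducials,
        "force_ch1": amplitude * pulse1,
        "force_ch2": amplitude * pulse2,
    }
    return PiezoRecording(
        ch1=channels[0],
        ch2=channels[1],
        fs=fs_per_channel,
        spacing_m=spacing,
        subject=subject,
        seed=subject.seed,
        truth=truth,
    )


def synth_hgcp_trajectory(
    subject: SubjectRecord,
    grip_s: float = 120.0,
    cold_s: float = 60.0,
    rest_s: float = 300.0,
    peak_sbp: float = 163.0,
    peak_dbp: float = 116.0,
    tau_s: float = 50.0,
    dt: float = 1.0,
) -> pd.DataFrame:
    """BP trajectory of a hand-grip + cold-pressor (HGCP) maneuver.

    Sustained hand grip ramps BP up slowly; the subsequent cold-pressor
    immersion drives a steeper rise to the configured peaks (defaults:
    the maneuver's maximum SBP 163 / DBP 116 mmHg); during rest BP
    relaxes exponentially back to the subject's baseline with time
    constant ``tau_s``.  Returns a DataFrame with columns t_s, sbp, dbp.
    """
    if min(grip_s, cold_s, rest_s) <= 0:
        raise ConfigurationError("all phase durations must be > 0")
    rows = []
    for base, peak in ((subject.sbp, peak_sbp), (subject.dbp, peak_dbp)):
        exc = peak - base
        mid = base + 0.5 * exc  # grip achieves half the excursion, cold the rest
        t_grip = np.arange(0.0, grip_s, dt)
        t_cold = np.arange(0.0, cold_s, dt)
        t_rest = np.arange(0.0, rest_s + dt / 2, dt)
        grip = base + (mid - base) * t_grip / grip_s
        cold = mid + (peak - mid) * t_cold / cold_s
        rest = base + (peak - base) * np.exp(-t_rest / tau_s)
        rows.append(np.concatenate([grip, cold, rest]))
    n = rows[0].size
    return pd.DataFrame({"t_s": np.arange(n) * dt, "sbp": rows[0], "dbp": rows[1]})
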