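"""Airbag pressure dynamics and the closed-loop adaptation controller.

The wearable presses its sensors against the artery with a micro airbag
inflated by a pump through a one-way valve.  Pumping happens in short
discrete phases (35 ms pulses, at least 3500 ms apart) of roughly equal
pressure increments, capped after 5 phases at 12 kPa (about 90 mmHg) so
the artery is never occluded; the hardware itself tolerates 40 kPa.
The valve retains pressure well but not perfectly: retention is modelled
as a single exponential calibrated so that 30% of the initial pressure
remains after one hour.

The closed-loop controller watches the signal-quality verdicts of
:func:`piezobp.preprocess.assess_quality`: on a distorted or absent
signal it fires one pumping phase (respecting the inter-phase interval);
once all phases are spent and quality is still poor it emits a single
relocation warning and stops inflating.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

from .errors import ConfigurationError, PhaseLimit
from .preprocess import QualityVerdict

__all__ = [
    "PumpSpec",
    "PumpState",
    "ControlEvent",
    "ControlTrace",
    "default_leak_tau_s",
    "inflate_phase",
    "leak",
    "closed_loop",
    "coupled_demo",
]


def default_leak_tau_s(retention: float = 0.30, horizon_s: float = 3600.0) -> float:
    """Leak time constant giving ``retention`` of initial pressure at ``horizon_s``.

    The one printed retention point (30% after 1 h) gives
    tau = 3600 / ln(1/0.30) ~= 2990.1 s.
    """
    if not 0 < retention < 1:
        raise ConfigurationError("retention must be in (0, 1)")
    return horizon_s / math.log(1.0 / retention)


@dataclass(frozen=True)
class PumpSpec:
    """Pump timing, per-phase increments, caps, and valve leak constant."""

    pulse_ms: float = 35.0
    interval_ms: float = 3500.0
    max_phases: int = 5
    cap_kpa: float = 12.0
    hardware_max_kpa: float = 40.0
    #: per-phase pressure increments; default: equal steps cap/max_phases
    schedule_kpa: tuple[float, ...] | None = None
    tau_s: float = field(default_factory=default_leak_tau_s)

    def __post_init__(self) -> None:
        if self.max_phases < 1:
            raise ConfigurationError("max_phases must be >= 1")
        if self.cap_kpa > self.hardware_max_kpa:
            raise ConfigurationError("pressure cap exceeds the hardware maximum")
        if self.tau_s <= 0:
            raise ConfigurationError("leak time constant must be > 0")
        if self.schedule_kpa is not None:
            if len(self.schedule_kpa) != self.max_phases:
                raise ConfigurationError("schedule length must equal max_phases")
            if sum(self.schedule_kpa) > self.hardware_max_kpa:
                raise ConfigurationError("schedule exceeds the hardware maximum")

    @property
    def increments(self) -> tuple[float, ...]:
        if self.schedule_kpa is not None:
            return self.schedule_kpa
        return tuple([self.cap_kpa / self.max_phases] * self.max_phases)


@dataclass(frozen=True)
class PumpState:
    """Controller state: airbag pressure, phase counter, clock, warning flag."""

    pressure_kpa: float = 0.0
    phases: int = 0
    t_s: float = 0.0
    warned: bool = False

    def __post_init__(self) -> None:
        if self.pressure_kpa < 0:
            raise ConfigurationError("pressure cannot be negative")


@dataclass(frozen=True)
class ControlEvent:
    t_s: float
    verdict: str  # ok | distorted | no_signal
    action: str  # none | inflate | warn
    pressure_kpa: float


@dataclass(frozen=True)
class ControlTrace:
    events: tuple[ControlEvent, ...]
    final: PumpState

    @property
    def inflations(self) -> int:
        return sum(e.action == "inflate" for e in self.events)

    @property
    def warnings(self) -> int:
        return sum(e.action == "warn" for e in self.events)


def inflate_phase(state: PumpState, spec: PumpSpec | None = None) -> PumpState:
    """Execute one pumping phase: add the scheduled increment, bump the counter."""
    spec = spec or PumpSpec()
    if state.phases >= spec.max_phases:
        raise PhaseLimit(f"already at the maximum of {spec.max_phases} pumping phases")
    pressure = min(state.pressure_kpa + spec.increments[state.phases], spec.hardware_max_kpa)
    return replace(state, pressure_kpa=pressure, phases=state.phases + 1)


def leak(state: PumpState, dt: float, spec: PumpSpec | None = None) -> PumpState:
    """One-way-valve leakage: exponential pressure decay over ``dt`` seconds."""
    spec = spec or PumpSpec()
    if dt < 0:
        raise ConfigurationError("dt must be >= 0")
    return replace(
        state,
        pressure_kpa=state.pressure_kpa * math.exp(-dt / spec.tau_s),
        t_s=state.t_s + dt,
    )


def closed_loop(
    quality_stream: Iterable[QualityVerdict | str],
    spec: PumpSpec | None = None,
    step_s: float | None = None,
    state: PumpState | None = None,
) -> ControlTrace:
    """Run the feedback controller over a stream of quality verdicts.

    Each verdict arrives ``step_s`` seconds apart (default: the pumping
    interval, 3.5 s); valve leakage is applied between steps.  A poor
    verdict triggers one pumping phase, provided a full inter-phase
    interval has elapsed since the previous one; once the phase counter
    saturates with quality still poor, a single relocation warning is
    emitted and inflation stops.
    """
    spec = spec or PumpSpec()
    step_s = step_s if step_s is not None else spec.interval_ms / 1000.0
    state = state or PumpState()
    events: list[ControlEvent] = []
    last_inflate_t: float | None = None
    first = True
    for verdict in quality_stream:
        status = verdict.status if isinstance(verdict, QualityVerdict) else str(verdict)
        if status not in ("ok", "distorted", "no_signal"):
            raise ConfigurationError(f"unknown quality status {status!r}")
        if not first:
            state = leak(state, step_s, spec)
        first = False
        action = "none"
        if status != "ok":
            interval_ok = (
                last_inflate_t is None
                or state.t_s - last_inflate_t >= spec.interval_ms / 1000.0 - 1e-9
            )
            if state.phases < spec.max_phases and interval_ok:
                state = inflate_phase(state, spec)
                last_inflate_t = state.t_s
                action = "inflate"
            elif state.phases >= spec.max_phases and not state.warned:
                state = replace(state, warned=True)
                action = "warn"
        events.append(ControlEvent(state.t_s, status, action, state.pressure_kpa))
    if not events:
        raise ConfigurationError("quality stream is empty")
    return ControlTrace(tuple(events), state)


def coupled_demo(
    threshold_phase: int,
    spec: PumpSpec | None = None,
    n_steps: int = 12,
    seed: int = 0,
    window_s: float = 5.0,
    fs: float = 500.0,
) -> ControlTrace:
    """Controller coupled to the simulator: inflation restores signal quality.

    The contact gain is a monotone step in backpressure: below the
    pressure reached after ``threshold_phase`` phases the pulse couples
    into the sensor at only 2% of its amplitude (buried in noise), above
    it at full amplitude.  The controller therefore inflates exactly
    ``threshold_phase`` times before the quality verdict turns ok — or
    warns if the threshold exceeds the phase budget.
    """
    from .preprocess import assess_quality
    from .simkit import CohortSpec, NoiseSpec, sample_cohort, synth_dual_piezo
    from .transduce import TimeSeries

    spec = spec or PumpSpec()
    if threshold_phase < 0:
        raise ConfigurationError("threshold phase must be >= 0")
    subject = sample_cohort(CohortSpec(), 1, seed)[0]
    if threshold_phase > spec.max_phases:
        pressure_needed = spec.hardware_max_kpa + 1.0  # unreachable: must end in a warning
    else:
        pressure_needed = sum(spec.increments[:threshold_phase])
    rng = np.random.default_rng(seed)

    # Clean full-contact signal; the sensor floor noise is a fixed fraction
    # of its amplitude, so a poorly coupled signal drowns in it.
    rec = synth_dual_piezo(
        subject, noise=NoiseSpec(white_sd=0.0), duration=window_s, fs_per_channel=fs
    )
    clean = rec.ch1
    noise_sd = 0.15 * float(np.ptp(clean))

    state = PumpState()
    events: list[ControlEvent] = []
    step_s = spec.interval_ms / 1000.0
    for k in range(n_steps):
        if k:
            state = leak(state, step_s, spec)
        # 1% tolerance absorbs inter-step valve leakage at the threshold.
        gain = 1.0 if state.pressure_kpa >= 0.99 * pressure_needed else 0.02
        noisy = gain * clean + rng.normal(0.0, noise_sd, clean.size)
        verdict = assess_quality(TimeSeries(noisy, fs))
        action = "none"
        if verdict.status != "ok":
            if state.phases < spec.max_phases:
                state = inflate_phase(state, spec)
                action = "inflate"
            elif not state.warned:
                state = replace(state, warned=True)
                action = "warn"
        events.append(ControlEvent(state.t_s, verdict.status, action, state.pressure_kpa))
        if verdict.status == "ok" and action == "none" and k >= threshold_phase:
            break
    return ControlTrace(tuple(events), state)
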