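"""Piezo voltage <-> blood-propagation force conversion.

A piezoelectric sensing element pressed over an artery outputs a voltage
whose relation to the dynamic loading force is, after lumping the
constitutive tensors of the material into scalar gains,

    F(t) = A * integral_0^t V(tau) dtau  -  B * V(t)  +  C

For PZT layers thicker than a few micrometres the integral term dominates,
so the default pipeline path uses the pure-integration form (B = 0, C = 0).
A and B are calibration constants with no published numeric values; force
is therefore carried in arbitrary units throughout.

The inverse transform (`force_to_piezo`) exists for the simulator's forward
model: given a known force waveform, what voltage would the sensor emit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .errors import ConfigurationError, DataError

__all__ = [
    "TransduceParams",
    "TimeSeries",
    "VoltageSeries",
    "ForceWaveform",
    "piezo_to_force",
    "integral_only",
    "force_to_piezo",
]


@dataclass(frozen=True)
class TransduceParams:
    """Lumped scalar gains of the voltage-to-force model.

    A : integral gain (force per volt-second), must be positive.
    B : proportional gain (force per volt), non-negative.
    C : constant offset (force units).
    """

    A: float = 1.0
    B: float = 0.0
    C: float = 0.0

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ConfigurationError(f"integral gain A must be > 0, got {self.A}")
        if self.B < 0:
            raise ConfigurationError(f"proportional gain B must be >= 0, got {self.B}")


@dataclass(frozen=True)
class TimeSeries:
    """Uniformly sampled signal with sampling rate and start time."""

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be > 0, got {self.fs}")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


# Semantic aliases: voltage in volts, force in arbitrary units.
VoltageSeries = TimeSeries
ForceWaveform = TimeSeries


def _check_finite(x: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(x)):
        raise DataError(f"{what} contains non-finite samples")


def piezo_to_force(v: VoltageSeries, p: TransduceParams | None = None) -> ForceWaveform:
    """Convert a measured voltage series to the force waveform.

    F[k] = A * cumtrapz(v)[k] - B * v[k] + C, evaluated at the input
    sampling rate with second-order (trapezoid) accuracy.
    """
    p = p or TransduceParams()
    if v.n < 2:
        raise DataError("need at least 2 samples to integrate")
    _check_finite(v.values, "voltage")
    integral = cumulative_trapezoid(v.values, dx=1.0 / v.fs, initial=0.0)
    f = p.A * integral - p.B * v.values + p.C
    return ForceWaveform(f, v.fs, v.t0)


def integral_only(v: VoltageSeries, A: float = 1.0) -> ForceWaveform:
    """Pure-integration conversion: the default path for thick PZT layers.

    Equivalent to ``piezo_to_force(v, TransduceParams(A, 0, 0))``.
    """
    return piezo_to_force(v, TransduceParams(A=A, B=0.0, C=0.0))


def force_to_piezo(f: ForceWaveform, p: TransduceParams | None = None) -> VoltageSeries:
    """Invert the voltage-to-force model (simulator forward transducer).

    For B = 0 the model reduces to V = F'/A, computed with fourth-order
    central differences (smooth in the Nyquist band, which matters for
    sub-sample transit-time work on the simulated voltage).

    For B > 0, differencing the trapezoid-discretised integral equation

        A * I[k] - B * V[k] + C = F[k],   I[k] = I[k-1] + dt*(V[k-1]+V[k])/2

    gives a first-order implicit recursion that is run backward in time:
    the forward direction is unstable (the underlying ODE
    B*V' = A*V - F' has a growing mode exp(A t / B)), while backward
    that mode decays geometrically away from the terminal sample, which
    is seeded with the derivative estimate.  The result is the *bounded*
    inverse: it reproduces F up to a constant force offset (a static
    preload, carrying no pulsatile information and removed by the
    downstream band-pass); pinning the offset exactly would re-admit
    the growing mode.
    """
    p = p or TransduceParams()
    if f.n < 2:
        raise DataError("need at least 2 samples to differentiate")
    _check_finite(f.values, "force")
    dt = 1.0 / f.fs
    if p.B == 0.0:
        v = _derivative(f.values - p.C, dt) / p.A
        return VoltageSeries(v, f.fs, f.t0)
    n = f.n
    dF = np.diff(f.values)
    lo = p.A * dt / 2.0 - p.B
    hi = p.A * dt / 2.0 + p.B
    v = np.empty(n)
    v[-1] = _derivative(f.values, dt)[-1] / p.A  # integral-dominated seed
    for k in range(n - 1, 0, -1):
        v[k - 1] = (dF[k - 1] - v[k] * lo) / hi
    return VoltageSeries(v, f.fs, f.t0)


def _derivative(x: np.ndarray, dt: float) -> np.ndarray:
    """Fourth-order central differences inside, second-order at the edges."""
    n = x.size
    if n < 5:
        return np.gradient(x, dt, edge_order=1 if n < 3 else 2)
    d = np.empty(n)
    d[2:-2] = (8.0 * (x[3:-1] - x[1:-3]) - (x[4:] - x[:-4])) / (12.0 * dt)
    d[0] = (-3.0 * x[0] + 4.0 * x[1] - x[2]) / (2.0 * dt)
    d[1] = (x[2] - x[0]) / (2.0 * dt)
    d[-2] = (x[-1] - x[-3]) / (2.0 * dt)
    d[-1] = (3.0 * x[-1] - 4.0 * x[-2] + x[-3]) / (2.0 * dt)
    return d
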