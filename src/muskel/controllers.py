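"""Controllers mapping model outputs and prescribed signals to muscle excitations.

Two controller families are provided: prescribed (preset) piecewise-linear
excitation signals, and a delayed stretch reflex that raises excitation in
proportion to the muscle's normalized fiber lengthening velocity sensed one
conduction delay in the past.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .components import ModelError

__all__ = [
    "ExcitationSignal",
    "ReflexParams",
    "DelayBuffer",
    "prescribed_excitation",
    "stretch_reflex_excitation",
]


@dataclass
class ExcitationSignal:
    """Piecewise-linear excitation breakpoints with constant extrapolation."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape or self.times.size == 0:
            raise ModelError("excitation signal needs matching 1-D times and values")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ModelError("excitation breakpoint times must be strictly increasing")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ModelError("excitation values must lie in [0, 1]")

    def __call__(self, t: float) -> float:
        return prescribed_excitation(self, t)


@dataclass
class ReflexParams:
    """Velocity-gain stretch reflex: u = clamp(u0 + G * max(v(t - d) - v_thr, 0), u0, 1)."""

    gain: float
    delay: float
    velocity_threshold: float = 0.0
    baseline: float = 0.0

    def __post_init__(self):
        if self.gain < 0 or self.delay < 0:
            raise ModelError("reflex gain and delay must be >= 0")
        if not 0.0 <= self.baseline <= 1.0:
            raise ModelError("reflex baseline excitation must lie in [0, 1]")


@dataclass
class DelayBuffer:
    """Ring of (time, value) samples with linear interpolation on read.

    Samples must be appended with nondecreasing times; reads before the
    oldest sample report an underrun so the caller can fall back to a
    baseline value.
    """

    times: list = field(default_factory=list)
    values: list = field(default_factory=list)
    underrun: bool = False

    def append(self, t: float, value: float) -> None:
        if self.times and t < self.times[-1] - 1e-15:
            raise ModelError("delay buffer times must be nondecreasing")
        if self.times and t <= self.times[-1]:
            self.values[-1] = value  # replace duplicate time stamp
            return
        self.times.append(t)
        self.values.append(value)

    def sample(self, t: float):
        """Linear interpolation; returns ``(value, ok)`` with ok False on underrun."""
        if not self.times or t < self.times[0]:
            self.underrun = True
            return (self.values[0] if self.values else 0.0), False
        if t >= self.times[-1]:
            return self.values[-1], True
        i = bisect.bisect_right(self.times, t)
        t0, t1 = self.times[i - 1], self.times[i]
        v0, v1 = self.values[i - 1], self.values[i]
        w = (t - t0) / (t1 - t0)
        return v0 + w * (v1 - v0), True


def prescribed_excitation(signal: ExcitationSignal, t: float) -> float:
    """Piecewise-linear interpolation of the breakpoints, constant beyond the
    ends, clamped to [0, 1]."""
    u = float(np.interp(t, signal.times, signal.values))
    return min(max(u, 0.0), 1.0)


def stretch_reflex_excitation(params: ReflexParams, buffer: DelayBuffer, t: float) -> float:
    """Reflex excitation from the stretch velocity sensed at ``t - delay``.

    Depends only on buffer samples at times <= t - delay; a buffer underrun
    (simulation shorter than the delay) yields the baseline and flags the
    buffer.
    """
    v, ok = buffer.sample(t - params.delay)
    if not ok:
        return params.baseline
    u = params.baseline + params.gain * max(v - params.velocity_threshold, 0.0)
    return min(max(u, params.baseline), 1.0)
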