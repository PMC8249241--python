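"""In-memory containers for current-clamp data.

A trace is a uniformly sampled array with its sampling rate in kHz and a
start time, so sample ``i`` sits at ``t0 + i / (1000 * sampling_rate)``
seconds.  A :class:`StimulusProtocol` describes the injected-current
waveform declaratively; :meth:`StimulusProtocol.segments` lays the
protocol out on the time axis so the simulator and the feature
extractors agree on where every pulse, ramp and pre-pulse sits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

from .errors import ConfigurationError, InputError

__all__ = [
    "VoltageTrace",
    "CurrentTrace",
    "SpikeTrain",
    "StimulusProtocol",
    "Segment",
]


@dataclass(frozen=True)
class _Trace:
    samples: np.ndarray
    sampling_rate: float  # kHz
    t0: float = 0.0  # s

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigurationError(f"sampling_rate must be positive, got {self.sampling_rate}")
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1:
            raise InputError("trace samples must be one-dimensional")

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / (self.sampling_rate * 1000.0)

    @property
    def duration(self) -> float:
        return self.samples.size * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) * self.dt

    def window_slice(self, window: tuple[float, float]) -> slice:
        """Sample slice covering ``[start, stop)`` in seconds."""
        start, stop = window
        if stop <= start:
            raise InputError(f"empty window {window}")
        lo = int(round((start - self.t0) / self.dt))
        hi = int(round((stop - self.t0) / self.dt))
        if lo < 0 or hi > self.samples.size:
            raise InputError(f"window {window} outside trace span [{self.t0}, {self.t0 + self.duration}]")
        return slice(lo, hi)


class VoltageTrace(_Trace):
    """Membrane potential in mV."""


class CurrentTrace(_Trace):
    """Clamp/injected current in pA."""


@dataclass(frozen=True)
class SpikeTrain:
    """Action-potential times (s) with the detection threshold that produced them."""

    spike_times: np.ndarray
    detection_threshold: float  # mV

    def __post_init__(self) -> None:
        object.__setattr__(self, "spike_times", np.asarray(self.spike_times, dtype=float))
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise InputError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.spike_times.size)

    def in_window(self, window: tuple[float, float]) -> np.ndarray:
        start, stop = window
        t = self.spike_times
        return t[(t >= start) & (t < stop)]


@dataclass(frozen=True)
class Segment:
    """A labeled span of the injected-current waveform."""

    phase: str  # baseline | pulse | prepulse | test | ramp_up | ramp_down
    start: float  # s
    stop: float  # s
    amplitude: float  # pA (target amplitude; ramps go 0 -> amplitude -> 0)

    @property
    def window(self) -> tuple[float, float]:
        return (self.start, self.stop)


@dataclass(frozen=True)
class StimulusProtocol:
    """Declarative current-clamp protocol from a fixed holding potential.

    kinds
    -----
    ``step``
        one pulse of ``pulse_s`` per amplitude, gaps between.
    ``hyperpol_series``
        identical layout, used for passive properties and sag (1-s
        hyperpolarizing pulses in small increments).
    ``rebound``
        per amplitude: 2-s hyperpolarizing pre-pulse immediately
        followed by a 1-s test pulse of ``test_amplitude``.
    ``ramp_updown``
        per amplitude: ascending then descending ramp, ``ramp_s`` each.
    """

    kind: Literal["step", "ramp_updown", "hyperpol_series", "rebound"]
    amplitudes: Sequence[float]  # pA
    pulse_s: float = 1.0
    gap_s: float = 0.5
    pre_s: float = 0.5
    ramp_s: float = 5.0
    prepulse_s: float = 2.0
    test_s: float = 1.0
    test_amplitude: float = 10.0
    holding_potential: float = -70.0  # mV

    def __post_init__(self) -> None:
        if not self.amplitudes:
            raise ConfigurationError("protocol needs at least one amplitude")
        for name in ("pulse_s", "gap_s", "pre_s", "ramp_s", "prepulse_s", "test_s"):
            if getattr(self, name) < 0 or not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite and nonnegative")
        if not all(np.isfinite(a) for a in self.amplitudes):
            raise ConfigurationError("amplitudes must be finite")

    def segments(self) -> list[Segment]:
        segs: list[Segment] = []
        t = 0.0
        segs.append(Segment("baseline", t, t + self.pre_s, 0.0))
        t += self.pre_s
        for amp in self.amplitudes:
            if self.kind in ("step", "hyperpol_series"):
                segs.append(Segment("pulse", t, t + self.pulse_s, amp))
                t += self.pulse_s
            elif self.kind == "rebound":
                segs.append(Segment("prepulse", t, t + self.prepulse_s, amp))
                t += self.prepulse_s
                segs.append(Segment("test", t, t + self.test_s, self.test_amplitude))
                t += self.test_s
            elif self.kind == "ramp_updown":
                segs.append(Segment("ramp_up", t, t + self.ramp_s, amp))
                t += self.ramp_s
                segs.append(Segment("ramp_down", t, t + self.ramp_s, amp))
                t += self.ramp_s
            segs.append(Segment("baseline", t, t + self.gap_s, 0.0))
            t += self.gap_s
        return segs

    @property
    def duration(self) -> float:
        return self.segments()[-1].stop

    def iter_sweeps(self) -> Iterator[tuple[float, list[Segment]]]:
        """Yield (amplitude, its non-baseline segments) per protocol sweep."""
        segs = [s for s in self.segments() if s.phase != "baseline"]
        per_sweep = {"step": 1, "hyperpol_series": 1, "rebound": 2, "ramp_updown": 2}[self.kind]
        for i, amp in enumerate(self.amplitudes):
            yield amp, segs[i * per_sweep : (i + 1) * per_sweep]

    def current_waveform(self, sampling_rate: float, t0: float = 0.0) -> CurrentTrace:
        """Render the protocol as an injected-current trace (pA)."""
        dt = 1.0 / (sampling_rate * 1000.0)
        n = int(round(self.duration / dt))
        current = np.zeros(n)
        times = t0 + np.arange(n) * dt
        for seg in self.segments():
            lo = int(round(seg.start / dt))
            hi = int(round(seg.stop / dt))
            if seg.phase in ("pulse", "prepulse", "test"):
                current[lo:hi] = seg.amplitude
            elif seg.phase == "ramp_up":
                current[lo:hi] = seg.amplitude * (times[lo:hi] - seg.start) / (seg.stop - seg.start)
            elif seg.phase == "ramp_down":
                current[lo:hi] = seg.amplitude * (seg.stop - times[lo:hi]) / (seg.stop - seg.start)
        return CurrentTrace(samples=current, sampling_rate=sampling_rate, t0=t0)
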