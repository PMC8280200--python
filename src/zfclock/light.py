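"""Piecewise-constant lighting schedules.

A lighting protocol is an ordered sequence of half-open segments
``[start, end)`` carrying a binary light level: 0 (darkness) or 1 (light).
Segments tile ``[0, total_duration)`` without gaps.  Switch instants belong
to the *new* segment, so the light function is right-continuous.  Queries
beyond the protocol's end hold the final level (with a warning) -- recording
grids occasionally overrun the nominal schedule by one sample.

By convention experiments start at the beginning of a dark phase, so
:func:`ld_cycle` puts darkness first unless told otherwise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LightProtocol",
    "Segment",
    "ld_cycle",
    "constant",
    "concat",
    "with_pulse",
    "light_value",
]


@dataclass(frozen=True)
class Segment:
    start: float
    end: float
    level: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment end {self.end} must exceed start {self.start}")
        if self.level not in (0, 1):
            raise ValueError(f"light level must be 0 or 1, got {self.level}")


@dataclass(frozen=True)
class LightProtocol:
    """An ordered, gap-free tiling of ``[0, total_duration)`` by light levels."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("protocol needs at least one segment")
        if abs(self.segments[0].start) > 1e-12:
            raise ValueError("first segment must start at t = 0")
        for a, b in zip(self.segments, self.segments[1:]):
            if abs(a.end - b.start) > 1e-9:
                raise ValueError(
                    f"segments must tile contiguously: gap between {a.end} and {b.start}"
                )

    @property
    def total_duration(self) -> float:
        return self.segments[-1].end

    @property
    def switch_times(self) -> np.ndarray:
        """Times at which the light level changes (segment starts after t=0)."""
        return np.array([s.start for s in self.segments[1:]])

    def light_value(self, t: float) -> int:
        """Light level at time ``t`` (hours); right-continuous at switches."""
        if t < 0:
            raise ValueError(f"negative time {t}")
        if t >= self.total_duration:
            warnings.warn(
                f"t={t} h is beyond the protocol end ({self.total_duration} h); "
                "holding the final light level",
                stacklevel=2,
            )
            return self.segments[-1].level
        starts = np.array([s.start for s in self.segments])
        idx = int(np.searchsorted(starts, t, side="right")) - 1
        return self.segments[idx].level

    def values_on_grid(self, n_steps: int, dt: float, t0: float = 0.0) -> np.ndarray:
        """Light level during each integration step.

        Step ``k`` covers ``[t0 + k*dt, t0 + (k+1)*dt)``; its level is the
        protocol value at the step start (segments are half-open, so this is
        exact whenever switch times fall on the step grid).
        """
        t = t0 + dt * np.arange(n_steps)
        if n_steps and t[-1] >= self.total_duration + 1e-9:
            warnings.warn(
                "integration grid extends beyond the protocol; holding final level",
                stacklevel=2,
            )
        starts = np.array([s.start for s in self.segments])
        levels = np.array([s.level for s in self.segments], dtype=np.float64)
        idx = np.clip(np.searchsorted(starts, t + 1e-12, side="right") - 1, 0, None)
        return levels[idx]

    def simplified(self) -> "LightProtocol":
        """Merge adjacent segments that share a level."""
        merged: list[Segment] = []
        for s in self.segments:
            if merged and merged[-1].level == s.level:
                merged[-1] = Segment(merged[-1].start, s.end, s.level)
            else:
                merged.append(s)
        return LightProtocol(tuple(merged))

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "segments": [
                {"start": s.start, "end": s.end, "level": s.level}
                for s in self.segments
            ]
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @staticmethod
    def from_dict(d: dict) -> "LightProtocol":
        """Build from a segment list or from named shortcuts.

        Supported shortcut forms::

            {"type": "ld", "light_h": 12, "dark_h": 12, "cycles": 3}
            {"type": "constant", "level": 0, "duration": 144}
            {"type": "sequence", "parts": [ ... ]}
        """
        kind = d.get("type")
        if kind is None:
            return LightProtocol(
                tuple(Segment(s["start"], s["end"], int(s["level"])) for s in d["segments"])
            )
        if kind == "ld":
            return ld_cycle(
                d["light_h"],
                d["dark_h"],
                d["cycles"],
                lights_on_first=d.get("lights_on_first", False),
            )
        if kind == "constant":
            return constant(d["level"], d["duration"])
        if kind == "sequence":
            parts = [LightProtocol.from_dict(p) for p in d["parts"]]
            out = parts[0]
            for p in parts[1:]:
                out = concat(out, p)
            return out
        raise ValueError(f"unknown protocol type {kind!r}")

    @staticmethod
    def from_json(text: str) -> "LightProtocol":
        return LightProtocol.from_dict(json.loads(text))


def ld_cycle(
    light_h: float, dark_h: float, n_cycles: int, lights_on_first: bool = False
) -> LightProtocol:
    """``n_cycles`` alternating light:dark cycles of period ``light_h + dark_h``.

    Darkness comes first by default, matching recordings that start at the
    beginning of the dark phase.
    """
    if light_h <= 0 or dark_h <= 0:
        raise ValueError("light and dark durations must be positive")
    if n_cycles < 1:
        raise ValueError("need at least one cycle")
    first, second = ((light_h, 1), (dark_h, 0)) if lights_on_first else ((dark_h, 0), (light_h, 1))
    segs = []
    t = 0.0
    for _ in range(n_cycles):
        segs.append(Segment(t, t + first[0], first[1]))
        t += first[0]
        segs.append(Segment(t, t + second[0], second[1]))
        t += second[0]
    return LightProtocol(tuple(segs))


def constant(level: int, duration: float) -> LightProtocol:
    """Constant darkness (``level=0``) or constant light (``level=1``)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return LightProtocol((Segment(0.0, duration, level),))


def concat(a: LightProtocol, b: LightProtocol) -> LightProtocol:
    """Append ``b`` after ``a`` (b's clock is shifted by a's duration)."""
    off = a.total_duration
    shifted = tuple(Segment(s.start + off, s.end + off, s.level) for s in b.segments)
    return LightProtocol(a.segments + shifted)


def with_pulse(base: LightProtocol, pulse_start: float, pulse_duration: float) -> LightProtocol:
    """Override the light level to 1 on ``[pulse_start, pulse_start + pulse_duration)``."""
    if pulse_duration <= 0:
        raise ValueError("pulse duration must be positive")
    p0, p1 = pulse_start, pulse_start + pulse_duration
    if p0 < 0 or p1 > base.total_duration + 1e-9:
        raise ValueError(
            f"pulse [{p0}, {p1}) lies outside the protocol [0, {base.total_duration})"
        )
    segs: list[Segment] = []
    for s in base.segments:
        lo, hi = max(s.start, p0), min(s.end, p1)
        if lo >= hi:  # no overlap with the pulse
            segs.append(s)
            continue
        if s.start < lo:
            segs.append(Segment(s.start, lo, s.level))
        segs.append(Segment(lo, hi, 1))
        if hi < s.end:
            segs.append(Segment(hi, s.end, s.level))
    return LightProtocol(tuple(segs)).simplified()


def light_value(protocol: LightProtocol, t: float) -> int:
    """Functional alias for :meth:`LightProtocol.light_value`."""
    return protocol.light_value(t)
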