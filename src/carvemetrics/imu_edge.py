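"""Edge-angle estimation from boot-mounted gyroscopes.

A carving run is segmented into turn windows from the boot's roll angular
velocity: the trace is aggressively low-pass filtered at 0.5 Hz and local
maxima mark the instants when the ski is flat on the snow (start/end of a
turn cycle).  Within each window the roll rate, re-filtered at 6 Hz, is
integrated to a roll (edge) angle; a linear endpoint-anchored correction
forces the angle to zero at both boundaries, removing the ramp produced by
any constant gyro bias.  The maximum over the first half of the window is
the downhill (outside-ski) peak edge angle, the magnitude of the minimum
over the second half the uphill (inside-ski) peak.

Right-boot traces are negated before processing so both sides share one
sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .signal_core import (
    DegenerateInputError,
    InvalidParameterError,
    UniformSeries,
    local_extrema,
    zero_lag_lowpass,
)

__all__ = [
    "KinematicTrace",
    "TurnWindow",
    "EdgeAngleResult",
    "DegenerateWindowError",
    "orient_trace",
    "segment_turns",
    "edge_angles",
    "compute_edge_angles",
]

SENSOR_RANGE_DEG_S = 2000.0


class DegenerateWindowError(ValueError):
    """A turn window is too short for edge-angle extraction."""


@dataclass(frozen=True)
class KinematicTrace:
    """One boot's roll angular-velocity trace (deg/s)."""

    roll_rate: UniformSeries
    side: str
    oriented: bool = False

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise InvalidParameterError(f"unknown side {self.side!r}")
        if np.any(np.abs(self.roll_rate.values) > SENSOR_RANGE_DEG_S):
            raise InvalidParameterError(
                f"roll rate exceeds sensor range +/-{SENSOR_RANGE_DEG_S:g} deg/s"
            )

    @property
    def sample_rate(self) -> float:
        return self.roll_rate.sample_rate


@dataclass(frozen=True)
class TurnWindow:
    start_index: int
    end_index: int
    start_time: float
    end_time: float

    def __post_init__(self) -> None:
        if not (self.start_index < self.end_index and self.end_time > self.start_time):
            raise ValueError("turn window must have positive duration")

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass(frozen=True)
class EdgeAngleResult:
    turn_index: int
    downhill_peak: float   # deg, >= 0, from the first half of the window
    uphill_peak: float     # deg, >= 0, from the second half of the window
    window: TurnWindow
    qc_valid: bool = True


def orient_trace(trace: KinematicTrace) -> KinematicTrace:
    """Normalize sign convention: left unchanged, right negated.

    Applying the orientation twice restores the original values (involution
    on right-side traces); an already-oriented trace is returned as is.
    """
    if trace.oriented:
        return trace
    if trace.side == "left":
        return replace(trace, oriented=True)
    flipped = replace(trace.roll_rate, values=-trace.roll_rate.values)
    return replace(trace, roll_rate=flipped, oriented=True)


def segment_turns(
    trace: KinematicTrace,
    cutoff: float = 0.5,
    min_separation: float = 1.0,
    prominence_factor: float = 0.25,
) -> list[TurnWindow]:
    """Turn windows between successive maxima of the 0.5-Hz-filtered roll rate.

    Each window spans one full roll cycle of the boot: the downhill (outside
    ski) phase followed by the uphill (inside ski) phase.  The peak prominence
    threshold is ``prominence_factor`` times the filtered signal's SD; turns
    shorter than ``min_separation`` seconds apart are merged by the detector.
    Fewer than two maxima yield an empty list.
    """
    t = orient_trace(trace)
    if t.roll_rate.duration < 4.0:
        raise DegenerateInputError("need at least 4 s of data to segment turns")
    filt = zero_lag_lowpass(t.roll_rate, cutoff)
    prom = prominence_factor * float(np.std(filt.values))
    maxima = local_extrema(filt, "maxima", min_separation, prom)
    windows = []
    for k in range(len(maxima) - 1):
        i, j = int(maxima[k]), int(maxima[k + 1])
        windows.append(
            TurnWindow(
                start_index=i,
                end_index=j,
                start_time=filt.start_time + i / filt.sample_rate,
                end_time=filt.start_time + j / filt.sample_rate,
            )
        )
    return windows


def _integrated_angle(rate: UniformSeries, window: TurnWindow) -> np.ndarray:
    """Trapezoidal integral of the roll rate over the window, linearly
    corrected so the angle is exactly zero at both boundaries (the ski is
    flat there by construction of the segmentation)."""
    seg = rate.values[window.start_index : window.end_index + 1]
    dt = 1.0 / rate.sample_rate
    theta = np.concatenate(([0.0], np.cumsum((seg[1:] + seg[:-1]) * 0.5 * dt)))
    ramp = np.linspace(0.0, theta[-1], theta.size)
    return theta - ramp


def edge_angles(
    trace: KinematicTrace,
    window: TurnWindow,
    cutoff: float = 6.0,
    turn_index: int = 0,
    _prefiltered: UniformSeries | None = None,
) -> EdgeAngleResult:
    """Per-turn downhill and uphill peak edge angles (degrees).

    The roll rate is low-pass filtered at ``cutoff`` (default 6 Hz) over the
    whole trace, integrated across the window, and endpoint-anchored so the
    angle is zero at both boundaries.  The window is split at its temporal
    midpoint: the maximum of the first half is the downhill peak, the
    magnitude of the minimum of the second half the uphill peak.

    QC: windows with duration outside [1, 10] s or a peak above 80 deg are
    flagged ``qc_valid=False``.
    """
    t = orient_trace(trace)
    if window.duration < 0.5:
        raise DegenerateWindowError(f"window of {window.duration:.3f} s is too short")
    if window.end_index >= len(t.roll_rate):
        raise InvalidParameterError("window extends past the end of the trace")
    rate = _prefiltered if _prefiltered is not None else zero_lag_lowpass(t.roll_rate, cutoff)
    theta = _integrated_angle(rate, window)
    half = theta.size // 2
    downhill = float(np.max(theta[: half + 1]))
    uphill = float(-np.min(theta[half:]))
    downhill, uphill = max(downhill, 0.0), max(uphill, 0.0)
    qc = 1.0 <= window.duration <= 10.0 and max(downhill, uphill) <= 80.0
    return EdgeAngleResult(turn_index, downhill, uphill, window, qc)


def compute_edge_angles(
    trace: KinematicTrace,
    windows: list[TurnWindow] | None = None,
    segmentation_cutoff: float = 0.5,
    angle_cutoff: float = 6.0,
) -> list[EdgeAngleResult]:
    """Segment (optionally) and extract edge angles with one 6-Hz filter pass."""
    t = orient_trace(trace)
    if windows is None:
        windows = segment_turns(t, cutoff=segmentation_cutoff)
    if not windows:
        return []
    rate = zero_lag_lowpass(t.roll_rate, angle_cutoff)
    return [
        edge_angles(t, w, angle_cutoff, turn_index=k, _prefiltered=rate)
        for k, w in enumerate(windows)
    ]
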