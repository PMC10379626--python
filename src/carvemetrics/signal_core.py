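"""Shared filtering and extremum-detection primitives.

Both sensor pipelines (boot-roll gyroscope and insole normal force) rest on
two operations: a zero-lag (bidirectional) low-pass Butterworth filter and a
thresholded local-extremum detector.  The filter is applied forward then
backward so the net phase shift is zero, which matters because turn boundaries
and force apices are read off the filtered trace as time points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "UniformSeries",
    "InvalidParameterError",
    "DegenerateInputError",
    "zero_lag_lowpass",
    "local_extrema",
]


class InvalidParameterError(ValueError):
    """A filter or detector parameter is outside its valid range."""


class DegenerateInputError(ValueError):
    """The input series is too short or otherwise unusable for the operation."""


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled scalar time series.

    Parameters
    ----------
    values : array-like
        Sensor samples. Must be finite and contain at least two samples.
    sample_rate : float
        Sampling frequency in Hz (> 0).
    start_time : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    sample_rate: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise DegenerateInputError("series must be 1-D with length >= 2")
        if not np.all(np.isfinite(v)):
            raise InvalidParameterError("series values must be finite")
        if not (self.sample_rate > 0):
            raise InvalidParameterError("sample_rate must be > 0")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return (len(self) - 1) / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self)) / self.sample_rate

    def slice(self, start_index: int, end_index: int) -> "UniformSeries":
        """Sub-series over ``[start_index, end_index]`` inclusive."""
        return UniformSeries(
            self.values[start_index : end_index + 1],
            self.sample_rate,
            self.start_time + start_index / self.sample_rate,
        )

    def truncate(self, max_duration: float) -> "UniformSeries":
        """First ``max_duration`` seconds of the series (at least 2 samples)."""
        n = int(round(max_duration * self.sample_rate)) + 1
        n = max(2, min(n, len(self)))
        return replace(self, values=self.values[:n])

    # -- CSV interchange: header ``time_s,value`` ---------------------------

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, rel_tol: float = 0.01) -> "UniformSeries":
        """Read a ``time_s,value`` CSV, inferring and validating the rate.

        The sample interval must be uniform to within ``rel_tol`` (default 1%).
        """
        df = pd.read_csv(path)
        if not {"time_s", "value"}.issubset(df.columns):
            raise InvalidParameterError(f"{path}: expected columns time_s,value")
        t = df["time_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise DegenerateInputError(f"{path}: need at least two samples")
        dt = np.diff(t)
        med = float(np.median(dt))
        if med <= 0 or np.any(np.abs(dt - med) > rel_tol * med):
            raise InvalidParameterError(f"{path}: non-uniform sampling")
        return cls(df["value"].to_numpy(dtype=float), 1.0 / med, float(t[0]))


def zero_lag_lowpass(
    series: UniformSeries, cutoff: float, order: int = 2
) -> UniformSeries:
    """Bidirectional (zero-phase) low-pass Butterworth filter.

    An ``order``-th order Butterworth design is applied forward then backward,
    so the effective magnitude response is the square of the single-pass
    response and the phase shift is exactly zero.  The nominal cutoff is used
    as designed, without double-pass attenuation correction.  Edges are
    handled with reflective (even) padding of roughly three characteristic
    lengths of the filter to suppress start-up transients.

    Raises
    ------
    InvalidParameterError
        If ``cutoff`` is not strictly between 0 and the Nyquist frequency, or
        ``order`` < 1.
    DegenerateInputError
        If the series is too short (length must exceed ``3 * order`` and the
        minimum stable ``filtfilt`` length).
    """
    fs = series.sample_rate
    if not (0.0 < cutoff < fs / 2.0):
        raise InvalidParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={fs / 2:g}) Hz"
        )
    if order < 1:
        raise InvalidParameterError("filter order must be >= 1")
    n = len(series)
    sos = sps.butter(order, cutoff, btype="low", fs=fs, output="sos")
    min_len = 3 * order + 1
    if n <= max(min_len, 7):
        raise DegenerateInputError(
            f"series of length {n} too short for order-{order} zero-lag filtering"
        )
    # Characteristic length ~ one cutoff period; capped by the series itself.
    padlen = int(min(n - 1, max(3 * order, np.ceil(3.0 * fs / cutoff))))
    filtered = sps.sosfiltfilt(sos, series.values, padtype="even", padlen=padlen)
    return replace(series, values=filtered)


def _candidate_extrema(values: np.ndarray, min_prominence: float):
    """All local maxima of ``values`` with their plateau-left index and height.

    Plateaus are reported at their first (leftmost) sample for deterministic
    tie-breaking.
    """
    peaks, props = sps.find_peaks(
        values,
        prominence=min_prominence if min_prominence > 0 else None,
        plateau_size=(1, None),
    )
    left = props["left_edges"]
    return left, values[peaks]


def local_extrema(
    series: UniformSeries,
    kind: str = "maxima",
    min_separation: float = 0.0,
    min_prominence: float = 0.0,
) -> np.ndarray:
    """Indices of interior local maxima or minima subject to two thresholds.

    Parameters
    ----------
    kind : {"maxima", "minima"}
    min_separation : float
        Minimum spacing between retained extrema, in seconds.  When two
        candidates conflict the one with the larger magnitude wins (ties go
        to the earlier index), matching the usual peak-picking convention.
    min_prominence : float
        Minimum topographic prominence, in signal units.

    Returns
    -------
    numpy.ndarray of int
        Strictly increasing sample indices; empty when nothing qualifies.
    """
    if kind not in ("maxima", "minima"):
        raise InvalidParameterError(f"kind must be 'maxima' or 'minima', got {kind!r}")
    if min_separation < 0 or min_prominence < 0:
        raise InvalidParameterError("thresholds must be non-negative")
    y = series.values if kind == "maxima" else -series.values
    idx, height = _candidate_extrema(y, min_prominence)
    if idx.size == 0 or min_separation == 0:
        return idx.astype(int)
    # Greedy pruning, tallest first (earlier index wins ties).
    min_gap = min_separation * series.sample_rate
    order = np.lexsort((idx, -height))
    keep: list[int] = []
    for i in order:
        if all(abs(idx[i] - idx[j]) >= min_gap for j in keep):
            keep.append(i)
    return np.sort(idx[keep]).astype(int)
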