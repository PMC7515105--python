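"""Time-series container used throughout :mod:`ordpat`.

A series is an ordered sequence of real values in which individual
entries may be missing.  Missing entries are represented internally by
IEEE NaN; every statistic in this package treats a comparison involving
NaN as undefined rather than as an ordering.  All user-facing indices
(window starts, excluded time points in messages) are 1-based, matching
the usual notation x_1, ..., x_T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TimeSeries", "MISSING", "as_values"]

#: Sentinel for a missing observation.
MISSING = float("nan")


@dataclass(frozen=True)
class TimeSeries:
    """An ordered univariate series with explicit missing entries.

    Parameters
    ----------
    values
        Sequence of floats; NaN marks a missing observation.  Stored as
        a read-only ``float64`` array.
    sample_rate
        Samples per second, retained when the series was read from
        audio; ``None`` for unit-free data.
    """

    values: np.ndarray
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 1:
            raise ValueError(f"series must be one-dimensional, got shape {arr.shape}")
        if arr.size < 1:
            raise ValueError("series must contain at least one value")
        if np.any(np.isinf(arr)):
            raise ValueError("series entries must be finite or NaN")
        arr = arr.copy()
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def reversed(self) -> "TimeSeries":
        """Time-reversed copy x_T, ..., x_1."""
        return TimeSeries(self.values[::-1], self.sample_rate)

    def negated(self) -> "TimeSeries":
        """Sign-flipped copy -x_1, ..., -x_T."""
        return TimeSeries(-self.values, self.sample_rate)


def as_values(series: "TimeSeries | np.ndarray | list") -> np.ndarray:
    """Return the underlying float array of a series-like object."""
    if isinstance(series, TimeSeries):
        return series.values
    arr = np.asarray(series, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("series must be one-dimensional")
    return arr
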