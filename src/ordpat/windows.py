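"""Sliding-window engine: statistics over (window x lag) matrices.

Long recordings are rarely stationary as a whole, so every statistic is
computed on short windows and assembled into a matrix with one column
per window and one row per lag -- the ordinal analogue of a
spectrogram.  Cells whose pattern frequencies are statistically
indistinguishable from white noise are flagged by the mask criterion
T * Delta^2 < threshold, where T is the window length in samples and
the default threshold is 15.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .patterns import count_patterns, frequencies
from .series import TimeSeries, as_values
from .stats import (
    ORDINAL_STATISTICS,
    VALUE_STATISTICS,
    classical_autocorrelation,
    order_statistics,
    spearman_autocorrelation,
)

__all__ = [
    "WindowSpec",
    "WindowMatrix",
    "make_windows",
    "window_matrix",
    "window_matrices",
    "write_window_matrix",
]

DEFAULT_MASK_THRESHOLD = 15.0


@dataclass(frozen=True)
class WindowSpec:
    """How to slice a long series into windows.

    ``mode="fixed"`` takes windows of ``window_length`` samples whose
    starts advance by ``step`` (step = window_length means
    non-overlapping); a trailing partial window is dropped.
    ``mode="zero_crossing"`` places boundaries at positive-to-negative
    zero crossings (x_t > 0 and x_{t+1} <= 0) and uses the spans
    between consecutive boundaries, which removes the margin artefacts
    of hard cuts for oscillating signals.
    """

    window_length: int
    d_grid: tuple[int, ...]
    step: int | None = None
    mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "zero_crossing"):
            raise ValueError(f"mode must be 'fixed' or 'zero_crossing', got {self.mode!r}")
        if self.window_length < 1:
            raise ValueError("window_length must be >= 1")
        step = self.window_length if self.step is None else self.step
        if not 1 <= step <= self.window_length:
            raise ValueError("step must satisfy 1 <= step <= window_length")
        object.__setattr__(self, "step", step)
        grid = tuple(int(d) for d in self.d_grid)
        if not grid:
            raise ValueError("d_grid must not be empty")
        if grid[0] < 1 or any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("d_grid must be strictly increasing positive integers")
        object.__setattr__(self, "d_grid", grid)
        if self.mode == "fixed" and max(grid) > (self.window_length - 1) / 2:
            raise ValueError(
                f"max lag {max(grid)} leaves no triple in windows of "
                f"length {self.window_length} (need d <= (L-1)/2)"
            )


@dataclass(frozen=True)
class WindowMatrix:
    """One statistic over (lag x window), plus the white-noise mask.

    ``values[i, j]`` is the statistic at lag ``d_grid[i]`` in window
    ``j``; ``mask[i, j]`` is True where the cell is noise-like
    (T * Delta^2 below the threshold) or undefined; ``n[i, j]`` is the
    number of valid triples in that cell.  ``starts`` are 1-based first
    sample indices of the windows.
    """

    statistic: str
    starts: np.ndarray
    window_lengths: np.ndarray
    d_grid: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    n: np.ndarray
    mask_threshold: float
    sample_rate: float | None = None


def make_windows(
    series: TimeSeries | np.ndarray, spec: WindowSpec
) -> list[tuple[int, TimeSeries]]:
    """Slice a series into windows; returns (1-based start, window) pairs.

    Raises
    ------
    ValueError
        Fixed mode: series shorter than one window.  Zero-crossing
        mode: fewer than two positive-to-negative crossings (no span).
    """
    x = as_values(series)
    rate = series.sample_rate if isinstance(series, TimeSeries) else None
    T = x.size
    if spec.mode == "fixed":
        if T < spec.window_length:
            raise ValueError(
                f"series of length {T} is shorter than one window "
                f"({spec.window_length} samples)"
            )
        starts = range(0, T - spec.window_length + 1, spec.step)
        return [
            (s + 1, TimeSeries(x[s : s + spec.window_length], rate)) for s in starts
        ]
    # zero_crossing: boundary at t where x_t > 0 and x_{t+1} <= 0
    with np.errstate(invalid="ignore"):
        crossing = (x[:-1] > 0) & (x[1:] <= 0)
    bounds = np.flatnonzero(crossing)  # 0-based index of x_t
    if bounds.size < 2:
        raise ValueError(
            "zero_crossing mode needs at least two positive-to-negative "
            f"crossings, found {bounds.size}"
        )
    out: list[tuple[int, TimeSeries]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        out.append((int(a) + 2, TimeSeries(x[a + 1 : b + 1], rate)))
    return out


def window_matrices(
    series: TimeSeries | np.ndarray,
    spec: WindowSpec,
    statistics: Sequence[str],
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
    entropy_base: str | int = "e",
) -> dict[str, WindowMatrix]:
    """Compute several statistics over (window x lag) in one pass.

    The pattern tallies of each cell are computed once and shared by
    all requested ordinal statistics; ``rho`` and ``spearman`` are
    computed from the windowed values directly.  The mask uses the
    window length in samples for T in the criterion T * Delta^2 <
    ``mask_threshold`` (the per-cell triple count is stored alongside
    for users who prefer the effective sample size).
    """
    for s in statistics:
        if s not in ORDINAL_STATISTICS and s not in VALUE_STATISTICS:
            known = sorted(set(ORDINAL_STATISTICS) | set(VALUE_STATISTICS))
            raise ValueError(f"unknown statistic {s!r}; choose from {known}")

    pairs = make_windows(series, spec)
    starts = np.array([s for s, _ in pairs], dtype=np.int64)
    wins = [w.values for _, w in pairs]
    lengths = np.array([w.size for w in wins], dtype=np.int64)
    rate = series.sample_rate if isinstance(series, TimeSeries) else None
    grid = np.asarray(spec.d_grid, dtype=np.int64)
    shape = (grid.size, len(wins))

    ordinal = [s for s in statistics if s in ORDINAL_STATISTICS]
    attrs = {s: ORDINAL_STATISTICS[s] for s in ordinal}
    vals = {s: np.full(shape, np.nan) for s in statistics}
    delta2 = np.full(shape, np.nan)
    n_cell = np.zeros(shape, dtype=np.int64)

    # delta2 is computed in every cell regardless of the requested
    # statistics because the mask needs it
    for j, w in enumerate(wins):
        for i, d in enumerate(grid):
            if w.size < d + 1:
                continue
            freq = frequencies(count_patterns(w, int(d)))
            if not freq.defined:
                continue
            st = order_statistics(freq, entropy_base)
            delta2[i, j] = st.delta2
            n_cell[i, j] = st.n
            for s in ordinal:
                vals[s][i, j] = getattr(st, attrs[s])
        for s in statistics:
            if s in VALUE_STATISTICS:
                fn = (classical_autocorrelation if s == "rho"
                      else spearman_autocorrelation)
                dmax = int(grid.max())
                if w.size >= 2 and np.count_nonzero(~np.isnan(w)) >= 2:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        prof = fn(w, min(dmax, w.size - 1))
                    for i, d in enumerate(grid):
                        if d <= prof.lags.size:
                            vals[s][i, j] = prof.values[d - 1]

    with np.errstate(invalid="ignore"):
        mask = ~(lengths[np.newaxis, :] * delta2 >= mask_threshold)

    return {
        s: WindowMatrix(
            statistic=s,
            starts=starts,
            window_lengths=lengths,
            d_grid=grid,
            values=vals[s],
            mask=mask.copy(),
            n=n_cell.copy(),
            mask_threshold=mask_threshold,
            sample_rate=rate,
        )
        for s in statistics
    }


def window_matrix(
    series: TimeSeries | np.ndarray,
    spec: WindowSpec,
    statistic: str,
    mask_threshold: float = DEFAULT_MASK_THRESHOLD,
    entropy_base: str | int = "e",
) -> WindowMatrix:
    """Single-statistic convenience wrapper around :func:`window_matrices`."""
    return window_matrices(series, spec, [statistic], mask_threshold,
                           entropy_base)[statistic]


def write_window_matrix(path, mat: WindowMatrix, mask_path=None) -> None:
    """Write a matrix as TSV (first column d, one column per window).

    A header comment line records window starts and the sample rate;
    the boolean mask goes to a sidecar TSV (``mask_path`` or
    ``<path>.mask.tsv``) in the same layout with 0/1 entries.
    """
    starts = ",".join(str(s) for s in mat.starts)
    rate = "NA" if mat.sample_rate is None else repr(float(mat.sample_rate))
    header = (f"# statistic={mat.statistic} mask_threshold={mat.mask_threshold} "
              f"sample_rate={rate} window_starts={starts}\n")
    cols = "\t".join(f"w{j + 1}" for j in range(mat.starts.size))
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(f"d\t{cols}\n")
        for i, d in enumerate(mat.d_grid):
            row = "\t".join(
                "NaN" if np.isnan(v) else repr(float(v)) for v in mat.values[i]
            )
            fh.write(f"{d}\t{row}\n")
    if mask_path is None:
        mask_path = str(path) + ".mask.tsv"
    with open(mask_path, "w") as fh:
        fh.write(header)
        fh.write(f"d\t{cols}\n")
        for i, d in enumerate(mat.d_grid):
            fh.write(f"{d}\t" + "\t".join(str(int(v)) for v in mat.mask[i]) + "\n")
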