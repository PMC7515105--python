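"""Order-pattern classification and counting.

A triple (x_t, x_{t+d}, x_{t+2d}) of pairwise distinct values realises
one of the six permutations of length three, written as a rank word:
digit i is the rank (1 = smallest) of the i-th value.  The triple
(0, 1, -1) is pattern 231, for instance, because the last value is the
smallest and the middle one the largest.  A triple containing a missing
value or any tie -- including a tie between the first and last value --
has no pattern.  Pairs (x_t, x_{t+d}) are classified the same way into
12 (up) and 21 (down).

Tallying these patterns at a fixed lag d over a whole series yields the
raw counts from which every ordinal statistic in this package derives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .series import TimeSeries, as_values

__all__ = [
    "PATTERNS",
    "classify_pair",
    "classify_triple",
    "count_patterns",
    "frequencies",
    "PatternCounts",
    "PatternFrequencies",
]

#: The six rank words of length three, in lexicographic order.
PATTERNS: tuple[str, ...] = ("123", "132", "213", "231", "312", "321")

# rank-word lookup keyed by 9*rank(a) + 3*rank(b) + rank(c), ranks 0..2
_CODE_TO_INDEX = {
    0 * 9 + 1 * 3 + 2: 0,  # 123
    0 * 9 + 2 * 3 + 1: 1,  # 132
    1 * 9 + 0 * 3 + 2: 2,  # 213
    1 * 9 + 2 * 3 + 0: 3,  # 231
    2 * 9 + 0 * 3 + 1: 4,  # 312
    2 * 9 + 1 * 3 + 0: 5,  # 321
}


def classify_triple(a: float, b: float, c: float) -> str | None:
    """Rank word of a value triple, or ``None`` when undefined.

    Undefined means: any value is NaN, or any two of the three values
    are exactly equal (the non-adjacent pair a == c counts as a tie).
    Equality is exact; no tolerance is applied.
    """
    if math.isnan(a) or math.isnan(b) or math.isnan(c):
        return None
    if a == b or b == c or a == c:
        return None
    # int() guards against numpy bools, whose "+" is logical
    ra = int(a > b) + int(a > c)
    rb = int(b > a) + int(b > c)
    rc = 3 - ra - rb
    return PATTERNS[_CODE_TO_INDEX[ra * 9 + rb * 3 + rc]]


def classify_pair(a: float, b: float) -> str | None:
    """``"12"`` if a < b, ``"21"`` if a > b, ``None`` on tie or NaN."""
    if math.isnan(a) or math.isnan(b):
        return None
    if a < b:
        return "12"
    if a > b:
        return "21"
    return None


@dataclass(frozen=True)
class PatternCounts:
    """Raw tallies of length-3 and length-2 patterns at one lag.

    ``n_pi`` maps each rank word to its count; ``n`` is the number of
    time points with a defined triple, ``n_prime`` the number with a
    defined pair.  Triples run over t = 1 .. T-2d, pairs over
    t = 1 .. T-d; both exclude ties and missing values independently.
    """

    lag: int
    n_pi: dict[str, int]
    n: int
    n12: int
    n21: int
    n_prime: int
    series_length: int

    def __post_init__(self) -> None:
        if self.n != sum(self.n_pi.values()):
            raise ValueError("n must equal the sum of the pattern counts")
        if self.n_prime != self.n12 + self.n21:
            raise ValueError("n_prime must equal n12 + n21")


@dataclass(frozen=True)
class PatternFrequencies:
    """Relative pattern frequencies p_pi = n_pi / n at one lag.

    All six ``p_pi`` are NaN when no triple is defined (n = 0), and
    ``p12``/``p21`` are NaN when no pair is defined.
    """

    lag: int
    p_pi: dict[str, float]
    p12: float
    p21: float
    n: int
    n_prime: int

    @property
    def defined(self) -> bool:
        return self.n > 0


def _triple_codes(x: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised pattern index (0..5) and validity mask for all triples."""
    a = x[: -2 * d]
    b = x[d:-d]
    c = x[2 * d :]
    with np.errstate(invalid="ignore"):
        valid = (
            ~np.isnan(a)
            & ~np.isnan(b)
            & ~np.isnan(c)
            & (a != b)
            & (b != c)
            & (a != c)
        )
        ra = (a > b).astype(np.int8) + (a > c)
        rb = (b > a).astype(np.int8) + (b > c)
    # map rank pair (ra, rb) to lexicographic pattern index
    lut = np.full(9, -1, dtype=np.int8)
    for code, idx in _CODE_TO_INDEX.items():
        lut[(code // 9) * 3 + (code // 3) % 3] = idx
    codes = lut[ra * 3 + rb]
    return codes, valid


def count_patterns(
    series: TimeSeries | np.ndarray,
    lag: int,
    *,
    restrict_pairs_to_triples: bool = False,
) -> PatternCounts:
    """Tally pair and triple patterns of a series at one lag.

    Parameters
    ----------
    series
        The input series; NaN entries are missing.
    lag
        Spacing d >= 1 between compared samples.
    restrict_pairs_to_triples
        When true, pairs (x_t, x_{t+d}) are tallied only at time points
        t = 1 .. T-2d where the triple is defined, so that the support
        of pairs and triples coincides (then n123 + n132 + n231 = n12
        holds exactly).  Default tallies pairs over their full range
        t = 1 .. T-d, independent of the triples.

    Raises
    ------
    ValueError
        If ``lag < 1`` or the series is too short to contain even one
        candidate pair (T < d + 1).  A series long enough for pairs but
        not for triples is valid and yields n = 0.
    """
    if lag < 1:
        raise ValueError(f"lag must be a positive integer, got {lag}")
    x = as_values(series)
    T = x.size
    if T < lag + 1:
        raise ValueError(
            f"series of length {T} has no pairs or triples at lag {lag} "
            f"(need T >= {lag + 1})"
        )

    counts = np.zeros(6, dtype=np.int64)
    if T >= 2 * lag + 1:
        codes, valid = _triple_codes(x, lag)
        counts = np.bincount(codes[valid], minlength=6).astype(np.int64)

    a = x[:-lag]
    b = x[lag:]
    with np.errstate(invalid="ignore"):
        up = a < b
        down = a > b
    if restrict_pairs_to_triples:
        if T < 2 * lag + 1:
            up = np.zeros(0, dtype=bool)
            down = np.zeros(0, dtype=bool)
        else:
            m = x.size - 2 * lag
            up, down = up[:m] & valid, down[:m] & valid
    n12 = int(up.sum())
    n21 = int(down.sum())

    return PatternCounts(
        lag=lag,
        n_pi={p: int(c) for p, c in zip(PATTERNS, counts)},
        n=int(counts.sum()),
        n12=n12,
        n21=n21,
        n_prime=n12 + n21,
        series_length=T,
    )


def frequencies(counts: PatternCounts) -> PatternFrequencies:
    """Relative pattern frequencies p_pi = n_pi / n from raw tallies.

    Degenerate tallies (n = 0 or n' = 0) yield NaN frequencies, which
    propagate through all downstream statistics.
    """
    if counts.n > 0:
        p_pi = {p: counts.n_pi[p] / counts.n for p in PATTERNS}
    else:
        p_pi = {p: float("nan") for p in PATTERNS}
    if counts.n_prime > 0:
        p12 = counts.n12 / counts.n_prime
        p21 = counts.n21 / counts.n_prime
    else:
        p12 = p21 = float("nan")
    return PatternFrequencies(
        lag=counts.lag,
        p_pi=p_pi,
        p12=p12,
        p21=p21,
        n=counts.n,
        n_prime=counts.n_prime,
    )
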