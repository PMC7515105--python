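"""Order correlation functions, permutation entropy and the variance
decomposition of the distance to white noise.

For a fixed lag d with pattern frequencies p_pi(d), the four order
correlation functions are

* up-down balance   beta(d)  = p123 - p321  (also p12 - p21),
* persistence       tau(d)   = p123 + p321 - 1/3,
* rotational asym.  gamma(d) = p213 + p231 - p132 - p312,
* up-down scaling   delta(d) = p132 + p213 - p231 - p312.

All four vanish for white noise, where each pattern has probability
1/6.  The squared Euclidean distance of the frequency vector from that
uniform point, Delta^2 = sum (p_pi - 1/6)^2, decomposes exactly as

    4 Delta^2 = 3 tau^2 + 2 beta^2 + gamma^2 + delta^2 + eps^2,

where eps = p132 + p231 - p213 - p312 vanishes for the probabilities of
a process with stationary increments but is a (small) finite-sample
residual for frequencies estimated from data.  Dividing each term by
4 Delta^2 gives the relative components, an analysis of variance of the
ordinal structure.  The turning rate TR = 2/3 - tau is the frequency of
local extrema, a roughness measure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .patterns import PatternFrequencies, count_patterns, frequencies
from .series import TimeSeries, as_values

__all__ = [
    "OrderStatistics",
    "CorrelationProfile",
    "DecompositionReport",
    "order_statistics",
    "decomposition_report",
    "profile",
    "classical_autocorrelation",
    "spearman_autocorrelation",
    "ORDINAL_STATISTICS",
    "write_profile",
]


@dataclass(frozen=True)
class OrderStatistics:
    """All scalar ordinal statistics of one series at one lag."""

    lag: int
    n: int
    n_prime: int
    beta_pairs: float     # p12 - p21, estimated from all defined pairs
    beta_triples: float   # p123 - p321, estimated from defined triples
    tau: float
    gamma: float
    delta: float
    delta2: float         # squared distance to the white-noise point
    entropy: float
    turning_rate: float
    epsilon: float        # finite-sample residual p132+p231-p213-p312
    rel_tau: float
    rel_beta: float
    rel_gamma: float
    rel_delta: float


#: Names accepted by :func:`profile` and the window engine, mapped to
#: :class:`OrderStatistics` attributes.  "beta" means the triple form,
#: which is the one entering the variance decomposition.
ORDINAL_STATISTICS: dict[str, str] = {
    "beta": "beta_triples",
    "beta_triples": "beta_triples",
    "beta_pairs": "beta_pairs",
    "tau": "tau",
    "gamma": "gamma",
    "delta": "delta",
    "delta2": "delta2",
    "entropy": "entropy",
    "H": "entropy",
    "turning_rate": "turning_rate",
    "tr": "turning_rate",
    "epsilon": "epsilon",
    "rel_tau": "rel_tau",
    "rel_beta": "rel_beta",
    "rel_gamma": "rel_gamma",
    "rel_delta": "rel_delta",
}

#: Comparison autocorrelations computed on values rather than patterns.
VALUE_STATISTICS = ("rho", "spearman")


def order_statistics(
    freq: PatternFrequencies, entropy_base: str | int = "e"
) -> OrderStatistics:
    """Compute every ordinal scalar statistic from pattern frequencies.

    Parameters
    ----------
    freq
        Defined pattern frequencies (n > 0 required).
    entropy_base
        ``"e"`` (default) for nats or ``2`` for bits.

    Raises
    ------
    ValueError
        If the frequencies are undefined (no valid triple).
    """
    if not freq.defined:
        raise ValueError(
            f"order statistics undefined at lag {freq.lag}: no valid triple"
        )
    p = freq.p_pi
    p123, p132, p213, p231, p312, p321 = (p[w] for w in
                                          ("123", "132", "213", "231", "312", "321"))

    beta_triples = p123 - p321
    tau = p123 + p321 - 1.0 / 3.0
    gamma = p213 + p231 - p132 - p312
    delta = p132 + p213 - p231 - p312
    epsilon = p132 + p231 - p213 - p312
    turning_rate = p132 + p213 + p231 + p312
    delta2 = sum((q - 1.0 / 6.0) ** 2 for q in p.values())

    if entropy_base in ("e", math.e):
        log = math.log
    elif entropy_base in (2, "2"):
        log = math.log2
    else:
        raise ValueError(f"entropy_base must be 'e' or 2, got {entropy_base!r}")
    entropy = -sum(q * log(q) for q in p.values() if q > 0.0)

    if delta2 > 0.0:
        rel_tau = 3.0 * tau**2 / (4.0 * delta2)
        rel_beta = beta_triples**2 / (2.0 * delta2)
        rel_gamma = gamma**2 / (4.0 * delta2)
        rel_delta = delta**2 / (4.0 * delta2)
    else:
        rel_tau = rel_beta = rel_gamma = rel_delta = float("nan")

    beta_pairs = (freq.p12 - freq.p21) if freq.n_prime > 0 else float("nan")

    return OrderStatistics(
        lag=freq.lag,
        n=freq.n,
        n_prime=freq.n_prime,
        beta_pairs=beta_pairs,
        beta_triples=beta_triples,
        tau=tau,
        gamma=gamma,
        delta=delta,
        delta2=delta2,
        entropy=entropy,
        turning_rate=turning_rate,
        epsilon=epsilon,
        rel_tau=rel_tau,
        rel_beta=rel_beta,
        rel_gamma=rel_gamma,
        rel_delta=rel_delta,
    )


@dataclass(frozen=True)
class DecompositionReport:
    """The Pythagoras-type split of 4*Delta^2 into squared components."""

    tau_component: float      # 3 tau^2
    beta_component: float     # 2 beta^2 (triple form)
    gamma_component: float    # gamma^2
    delta_component: float    # delta^2
    epsilon_component: float  # eps^2
    four_delta2: float
    residual: float           # 4D^2 - 3t^2 - 2b^2 - g^2 - d^2 - e^2


def decomposition_report(stats: OrderStatistics) -> DecompositionReport:
    """Split 4*Delta^2 into its four variance components plus residual.

    The residual is an algebraic zero whenever the six frequencies sum
    to one, so on real tallies it only carries floating-point error.
    """
    t = 3.0 * stats.tau**2
    b = 2.0 * stats.beta_triples**2
    g = stats.gamma**2
    d = stats.delta**2
    e = stats.epsilon**2
    lhs = 4.0 * stats.delta2
    return DecompositionReport(
        tau_component=t,
        beta_component=b,
        gamma_component=g,
        delta_component=d,
        epsilon_component=e,
        four_delta2=lhs,
        residual=lhs - t - b - g - d - e,
    )


@dataclass(frozen=True)
class CorrelationProfile:
    """One statistic evaluated over a grid of lags d = 1 .. d_max."""

    statistic: str
    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=np.int64)
        vals = np.asarray(self.values, dtype=np.float64)
        if lags.shape != vals.shape:
            raise ValueError("lags and values must have equal length")
        if lags.size and (np.any(np.diff(lags) <= 0) or lags[0] < 1):
            raise ValueError("lag grid must be strictly increasing positive integers")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", vals)


def _check_dmax(T: int, d_max: int) -> None:
    if d_max < 1:
        raise ValueError(f"d_max must be >= 1, got {d_max}")
    if d_max > T / 6:
        warnings.warn(
            f"d_max={d_max} exceeds T/6 = {T / 6:.0f}; estimates at large "
            "lags rest on few triples",
            stacklevel=3,
        )


def profile(
    series: TimeSeries | np.ndarray,
    statistic: str,
    d_max: int,
    entropy_base: str | int = "e",
) -> CorrelationProfile:
    """Evaluate an ordinal statistic (or rho/Spearman) at d = 1 .. d_max.

    Lags where the statistic is undefined (no valid triple, or an
    attribution at Delta^2 = 0) carry NaN.
    """
    x = as_values(series)
    _check_dmax(x.size, d_max)
    if statistic in VALUE_STATISTICS:
        fn = (classical_autocorrelation if statistic == "rho"
              else spearman_autocorrelation)
        return fn(series, d_max)
    if statistic not in ORDINAL_STATISTICS:
        known = sorted(set(ORDINAL_STATISTICS) | set(VALUE_STATISTICS))
        raise ValueError(f"unknown statistic {statistic!r}; choose from {known}")
    attr = ORDINAL_STATISTICS[statistic]

    values = np.full(d_max, np.nan)
    for d in range(1, d_max + 1):
        if x.size < d + 1:
            break
        freq = frequencies(count_patterns(x, d))
        if not freq.defined:
            continue
        values[d - 1] = getattr(order_statistics(freq, entropy_base), attr)
    return CorrelationProfile(statistic, np.arange(1, d_max + 1), values)


def _lagged_pairs(x: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    a, b = x[:-d], x[d:]
    ok = ~np.isnan(a) & ~np.isnan(b)
    return a[ok], b[ok]


def classical_autocorrelation(
    series: TimeSeries | np.ndarray, d_max: int
) -> CorrelationProfile:
    """Pearson correlation of the series with its copy shifted by d.

    Pairs with a missing member are deleted (pairwise deletion, no
    imputation).  Lags with fewer than two complete pairs or with zero
    variance in either margin yield NaN.
    """
    x = as_values(series)
    if np.count_nonzero(~np.isnan(x)) < 2:
        raise ValueError("need at least two non-missing values")
    _check_dmax(x.size, d_max)
    values = np.full(d_max, np.nan)
    for d in range(1, d_max + 1):
        if x.size < d + 1:
            break
        a, b = _lagged_pairs(x, d)
        if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        values[d - 1] = float(np.corrcoef(a, b)[0, 1])
    return CorrelationProfile("rho", np.arange(1, d_max + 1), values)


def spearman_autocorrelation(
    series: TimeSeries | np.ndarray, d_max: int
) -> CorrelationProfile:
    """Spearman rank correlation of the series with its shifted copy.

    Mid-ranks over the complete pairs; pairwise deletion as in
    :func:`classical_autocorrelation`.
    """
    x = as_values(series)
    if np.count_nonzero(~np.isnan(x)) < 2:
        raise ValueError("need at least two non-missing values")
    _check_dmax(x.size, d_max)
    values = np.full(d_max, np.nan)
    for d in range(1, d_max + 1):
        if x.size < d + 1:
            break
        a, b = _lagged_pairs(x, d)
        if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
            continue
        values[d - 1] = float(sps.spearmanr(a, b).statistic)
    return CorrelationProfile("spearman", np.arange(1, d_max + 1), values)


def write_profile(path, prof: CorrelationProfile) -> None:
    """Write a profile as TSV with header ``d<TAB><statistic>``.

    Undefined lags are written as ``NaN``; the decimal separator is
    always '.' regardless of locale.
    """
    with open(path, "w") as fh:
        fh.write(f"d\t{prof.statistic}\n")
        for d, v in zip(prof.lags, prof.values):
            fh.write(f"{d}\t{'NaN' if np.isnan(v) else repr(float(v))}\n")
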