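"""Shared fixtures and the independent brute-force pattern counter.

The brute-force counter classifies each triple by sorting its three
values and building the rank word explicitly, one Python loop step at a
time.  It shares no code with the vectorised counter in
:mod:`ordpat.patterns` and serves as the oracle in equivalence tests.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ordpat import TimeSeries
from ordpat.synthetic import FIXTURE_FIG3


def brute_force_counts(values, d):
    """Reference tally of pair/triple patterns via explicit sorting.

    Returns (n_pi dict, n, n12, n21) computed entirely independently of
    the production counter.
    """
    x = [float(v) for v in values]
    T = len(x)
    n_pi = {p: 0 for p in ("123", "132", "213", "231", "312", "321")}
    for t in range(T - 2 * d):
        triple = (x[t], x[t + d], x[t + 2 * d])
        if any(math.isnan(v) for v in triple):
            continue
        if len(set(triple)) < 3:
            continue
        order = sorted(range(3), key=lambda i: triple[i])
        ranks = [0, 0, 0]
        for r, i in enumerate(order, start=1):
            ranks[i] = r
        n_pi["".join(str(r) for r in ranks)] += 1
    n12 = n21 = 0
    for t in range(T - d):
        a, b = x[t], x[t + d]
        if math.isnan(a) or math.isnan(b) or a == b:
            continue
        if a < b:
            n12 += 1
        else:
            n21 += 1
    return n_pi, sum(n_pi.values()), n12, n21


def random_gappy_series(rng, min_len=50, max_len=500):
    """A random series with injected exact ties and missing entries."""
    T = int(rng.integers(min_len, max_len + 1))
    x = rng.normal(size=T)
    n_missing = int(rng.integers(0, max(1, T // 10)))
    n_ties = int(rng.integers(0, max(1, T // 10)))
    if n_ties:
        idx = rng.choice(np.arange(1, T), size=min(n_ties, T - 1), replace=False)
        x[idx] = x[idx - 1]
    if n_missing:
        idx = rng.choice(T, size=n_missing, replace=False)
        x[idx] = np.nan
    return x


@pytest.fixture
def fig3():
    """The ten-point worked-example series (missing x2, tie x5=x9=x10)."""
    return TimeSeries(np.array(FIXTURE_FIG3))


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
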