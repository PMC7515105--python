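"""Order correlation functions, entropy, decomposition and symmetries."""

import math

import numpy as np
import pytest

from ordpat import (
    TimeSeries,
    classical_autocorrelation,
    count_patterns,
    decomposition_report,
    frequencies,
    order_statistics,
    profile,
    spearman_autocorrelation,
)
from ordpat.patterns import PATTERNS, PatternFrequencies
from conftest import random_gappy_series


def stats_at(x, d, **kw):
    return order_statistics(frequencies(count_patterns(x, d)), **kw)


def make_freq(p, p12=0.5, p21=0.5, n=100):
    return PatternFrequencies(
        lag=1, p_pi=dict(zip(PATTERNS, p)), p12=p12, p21=p21, n=n, n_prime=n
    )


class TestWorkedExample:
    def test_scalar_statistics(self, fig3):
        s = stats_at(fig3, 1)
        assert s.beta_pairs == 0.0
        assert s.beta_triples == pytest.approx(-1 / 5, abs=1e-15)
        assert s.tau == pytest.approx(-2 / 15, abs=1e-15)
        assert s.gamma == pytest.approx(-2 / 5, abs=1e-15)
        assert s.delta == pytest.approx(-2 / 5, abs=1e-15)
        assert s.delta2 == pytest.approx(17 / 150, abs=1e-15)
        assert s.epsilon == 0.0
        s2 = stats_at(fig3, 2)
        assert s2.beta_pairs == pytest.approx(-1 / 7, abs=1e-15)
        assert s2.beta_triples == pytest.approx(-1 / 4, abs=1e-15)

    def test_decomposition_components(self, fig3):
        rep = decomposition_report(stats_at(fig3, 1))
        assert rep.tau_component == pytest.approx(4 / 75, abs=1e-15)
        assert rep.beta_component == pytest.approx(6 / 75, abs=1e-15)
        assert rep.gamma_component == pytest.approx(12 / 75, abs=1e-15)
        assert rep.delta_component == pytest.approx(12 / 75, abs=1e-15)
        assert rep.epsilon_component == 0.0
        assert rep.four_delta2 == pytest.approx(34 / 75, abs=1e-15)
        assert abs(rep.residual) <= 1e-12


def test_white_noise_point():
    """Uniform frequencies are the origin of the coordinate system."""
    s = order_statistics(make_freq([1 / 6] * 6))
    assert s.beta_triples == s.gamma == s.delta == 0.0
    assert s.tau == pytest.approx(0.0, abs=1e-15)
    assert s.delta2 == pytest.approx(0.0, abs=1e-15)
    assert s.epsilon == 0.0
    assert s.entropy == pytest.approx(math.log(6), abs=1e-12)
    assert s.turning_rate == pytest.approx(2 / 3, abs=1e-15)
    # attribution of zero distance is undefined, not zero
    assert math.isnan(s.rel_tau) and math.isnan(s.rel_beta)


def test_entropy_base_2():
    s = order_statistics(make_freq([1 / 6] * 6), entropy_base=2)
    assert s.entropy == pytest.approx(math.log2(6), abs=1e-12)
    with pytest.raises(ValueError, match="entropy_base"):
        order_statistics(make_freq([1 / 6] * 6), entropy_base=10)


def test_monotone_point():
    s = order_statistics(make_freq([1, 0, 0, 0, 0, 0], p12=1.0, p21=0.0))
    assert s.tau == pytest.approx(2 / 3, abs=1e-15)
    assert s.turning_rate == 0.0
    assert s.delta2 == pytest.approx(5 / 6, abs=1e-15)
    assert s.entropy == 0.0  # 0 log 0 = 0


def test_undefined_frequencies_raise():
    bad = PatternFrequencies(
        lag=1, p_pi={p: float("nan") for p in PATTERNS},
        p12=float("nan"), p21=float("nan"), n=0, n_prime=0,
    )
    with pytest.raises(ValueError, match="undefined"):
        order_statistics(bad)


def test_exact_identities_on_random_series(rng):
    """TR = 2/3 - tau and the Pythagoras split hold on every tally."""
    for _ in range(100):
        x = random_gappy_series(rng, 30, 300)
        for d in (1, 2, 5):
            f = frequencies(count_patterns(x, d))
            if not f.defined:
                continue
            s = order_statistics(f)
            assert s.turning_rate == pytest.approx(2 / 3 - s.tau, abs=1e-12)
            rep = decomposition_report(s)
            assert abs(rep.residual) <= 1e-12
            if s.delta2 > 0:
                total = s.rel_tau + s.rel_beta + s.rel_gamma + s.rel_delta
                assert total == pytest.approx(
                    1 - s.epsilon**2 / (4 * s.delta2), abs=1e-9
                )


def test_tau_matches_difference_form(rng):
    """tau as p123 + p321 - 1/3 equals its all-pattern difference form."""
    x = random_gappy_series(rng, 100, 300)
    f = frequencies(count_patterns(x, 1))
    p = f.p_pi
    alt = (2 * p["123"] + 2 * p["321"]
           - p["132"] - p["213"] - p["231"] - p["312"]) / 3
    assert order_statistics(f).tau == pytest.approx(alt, abs=1e-12)


class TestSymmetries:
    """Behaviour under time reversal, negation and their combination.

    Persistence (and the even aggregates) are invariant under all
    three; the odd functions beta, gamma, delta flip under reversal;
    negation flips beta and delta but not gamma; the combined rotation
    flips only gamma.
    """

    @pytest.fixture()
    def pairs(self, rng):
        out = []
        for _ in range(30):
            x = TimeSeries(random_gappy_series(rng, 50, 200))
            d = int(rng.integers(1, 5))
            out.append((x, d))
        return out

    def test_time_reversal(self, pairs):
        for x, d in pairs:
            s, r = stats_at(x, d), stats_at(x.reversed(), d)
            assert r.tau == pytest.approx(s.tau, abs=1e-12)
            assert r.delta2 == pytest.approx(s.delta2, abs=1e-12)
            assert r.entropy == pytest.approx(s.entropy, abs=1e-12)
            assert r.turning_rate == pytest.approx(s.turning_rate, abs=1e-12)
            assert r.beta_triples == pytest.approx(-s.beta_triples, abs=1e-12)
            assert r.gamma == pytest.approx(-s.gamma, abs=1e-12)
            assert r.delta == pytest.approx(-s.delta, abs=1e-12)

    def test_negation(self, pairs):
        for x, d in pairs:
            s, m = stats_at(x, d), stats_at(x.negated(), d)
            assert m.tau == pytest.approx(s.tau, abs=1e-12)
            assert m.gamma == pytest.approx(s.gamma, abs=1e-12)
            assert m.beta_triples == pytest.approx(-s.beta_triples, abs=1e-12)
            assert m.delta == pytest.approx(-s.delta, abs=1e-12)

    def test_rotation(self, pairs):
        for x, d in pairs:
            s = stats_at(x, d)
            r = stats_at(x.reversed().negated(), d)
            assert r.tau == pytest.approx(s.tau, abs=1e-12)
            assert r.gamma == pytest.approx(-s.gamma, abs=1e-12)
            assert r.beta_triples == pytest.approx(s.beta_triples, abs=1e-12)
            assert r.delta == pytest.approx(s.delta, abs=1e-12)

    def test_rho_and_spearman_invariant_under_negation(self, rng):
        x = rng.normal(size=300).cumsum()
        for prof in (classical_autocorrelation, spearman_autocorrelation):
            a = prof(x, 5).values
            b = prof(-x, 5).values
            np.testing.assert_allclose(a, b, atol=1e-12)


class TestUpDownScalingIdentity:
    """delta(d) = beta(2d) - beta(d) across scales."""

    def test_exact_on_common_support(self, rng):
        # beta(2d) from the first-vs-third comparison of the lag-d
        # triples, beta(d) in triple form: the identity is then exact
        for _ in range(50):
            x = random_gappy_series(rng, 50, 300)
            d = int(rng.integers(1, 6))
            c = count_patterns(x, d)
            if c.n == 0:
                continue
            s = order_statistics(frequencies(c))
            beta_2d = (c.n_pi["123"] + c.n_pi["132"] + c.n_pi["213"]
                       - c.n_pi["231"] - c.n_pi["312"] - c.n_pi["321"]) / c.n
            assert s.delta == pytest.approx(beta_2d - s.beta_triples, abs=1e-12)

    def test_marginal_error_on_full_profiles(self, rng):
        # unrestricted estimates agree up to a margin-driven O(d/n) error
        x = rng.normal(size=5000).cumsum()
        beta = profile(x, "beta", 20).values
        delta = profile(x, "delta", 10).values
        for d in range(1, 11):
            assert delta[d - 1] == pytest.approx(
                beta[2 * d - 1] - beta[d - 1], abs=0.02
            )


class TestProfiles:
    def test_monotone_tau_profile(self):
        prof = profile(np.arange(1.0, 101.0), "tau", 10)
        np.testing.assert_allclose(prof.values, 2 / 3, atol=1e-12)
        assert list(prof.lags) == list(range(1, 11))

    def test_unknown_statistic(self):
        with pytest.raises(ValueError, match="unknown statistic"):
            profile(np.arange(50.0), "kendall", 5)

    def test_large_dmax_warns_and_pads_with_nan(self):
        x = np.arange(1.0, 11.0)
        with pytest.warns(UserWarning, match="T/6"):
            prof = profile(x, "tau", 5)
        assert np.isfinite(prof.values[:4]).all()
        assert np.isnan(prof.values[4])  # T < 2d+1: no triple at d = 5

    def test_statistic_aliases(self):
        x = np.arange(1.0, 101.0)
        assert profile(x, "H", 3).values == pytest.approx(
            profile(x, "entropy", 3).values
        )
        assert profile(x, "beta", 3).values == pytest.approx(
            profile(x, "beta_triples", 3).values
        )


class TestComparisonAutocorrelations:
    def test_alternating_series(self):
        x = (-1.0) ** np.arange(1, 101)
        rho = classical_autocorrelation(x, 2).values
        assert rho[0] == pytest.approx(-1.0, abs=1e-12)
        assert rho[1] == pytest.approx(1.0, abs=1e-12)
        sp = spearman_autocorrelation(x, 2).values
        assert sp[1] == pytest.approx(1.0, abs=1e-12)

    def test_monotone_series(self):
        # a monotone trend makes the series and its shifted copy move
        # together, so the lagged-copy correlation is +1 for increasing
        # AND decreasing series (only beta distinguishes the direction)
        up = np.arange(1.0, 101.0)
        assert spearman_autocorrelation(up, 1).values[0] == pytest.approx(1.0)
        assert spearman_autocorrelation(-up, 1).values[0] == pytest.approx(1.0)
        assert classical_autocorrelation(up, 1).values[0] == pytest.approx(1.0)
        assert classical_autocorrelation(-up, 1).values[0] == pytest.approx(1.0)

    def test_white_noise_is_uncorrelated(self, rng):
        x = rng.uniform(size=10**5)
        assert abs(classical_autocorrelation(x, 1).values[0]) < 0.02

    def test_pairwise_deletion(self, rng):
        x = rng.normal(size=200)
        x[::7] = np.nan
        vals = classical_autocorrelation(x, 3).values
        assert np.isfinite(vals).all()

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="non-missing"):
            classical_autocorrelation(np.full(10, np.nan), 2)
        # zero variance in a margin -> undefined, not an error
        vals = classical_autocorrelation(np.ones(10), 2).values
        assert np.isnan(vals).all()
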