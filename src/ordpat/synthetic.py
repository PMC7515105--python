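"""Synthetic test signals with known ordinal structure.

Every model here has a known signature in the order correlation
functions, so the whole toolkit can be exercised without external data:

``white_noise``
    iid Uniform(0, 1); all six pattern probabilities equal 1/6, every
    order correlation is zero, the turning rate is 2/3.
``gaussian_ar1``
    Stationary Gaussian AR(1), x_{t+1} = phi x_t + innovation.  The
    process is reversible, so beta, gamma and delta vanish at every lag
    while persistence is positive for phi > 0.
``noisy_sine``
    sin(2 pi t / L) plus additive Gaussian noise: persistence has a
    sharp minimum near -1/3 at the half period and a "bumped maximum"
    (local dip between two peaks) at the full period; the odd functions
    beta, gamma, delta cross zero at both.
``monotone``
    x_t = t; every triple is 123, so tau = 2/3 and the turning rate is 0.
``alternating``
    x_t = (-1)^t + 0.1 * Uniform(0,1) jitter (the jitter avoids exact
    ties); tau(1) is close to its minimum -1/3.
``updown_scaling_extremal``
    x_t = +/-(t + (-1)^t), the zig-zag ramp whose lag-1 triples
    alternate between 132 and 213, driving |delta(1)| to 1.
``rotation_extremal``
    x_t = base^t with base -2 or -1/2; lag-1 triples alternate between
    231 and 213 (resp. 132 and 312), driving |gamma(1)| to 1.
``fixture_fig3``
    The ten-point worked example [4, NaN, 7, 9, 5, 8, 6, 2, 5, 5] with
    one missing value and a triple tie; its tallies and both up-down
    balance estimators at lags 1 and 2 are known exactly and serve as
    the canonical cross-check fixture.  (This concrete series is a
    synthetic reconstruction: it was built to satisfy all the published
    constraints of the worked example, whose raw values are only shown
    graphically.)

Identical spec + seed always yields a bit-identical series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import MISSING, TimeSeries

__all__ = ["SyntheticSpec", "generate", "MODELS", "FIXTURE_FIG3"]

MODELS = (
    "white_noise",
    "gaussian_ar1",
    "noisy_sine",
    "monotone",
    "alternating",
    "updown_scaling_extremal",
    "rotation_extremal",
    "fixture_fig3",
)

#: The worked-example fixture (synthetic reconstruction, see module doc).
FIXTURE_FIG3 = (4.0, MISSING, 7.0, 9.0, 5.0, 8.0, 6.0, 2.0, 5.0, 5.0)

_AR1_BURN_IN = 1000


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic series.

    Parameters
    ----------
    model
        One of :data:`MODELS`.
    length
        Number of samples T.
    seed
        Seed for all randomness (innovations, jitter, injected gaps).
    phi
        AR(1) coefficient, |phi| < 1 (``gaussian_ar1`` only).
    period
        Period L in samples (``noisy_sine`` only).
    noise_amplitude
        Standard deviation of the additive Gaussian noise of
        ``noisy_sine``.  The default 0.2236 ~ sqrt(0.05) puts the noise
        power at one tenth of the unit sine's power (SNR 10).
    sign
        +1 or -1: flips ``updown_scaling_extremal``; selects base -2
        (+1) or -1/2 (-1) for ``rotation_extremal``.
    missing_fraction
        Fraction of entries replaced by NaN after generation.
    tie_fraction
        Fraction of entries overwritten with their left neighbour's
        value, creating exact ties.
    """

    model: str
    length: int
    seed: int = 0
    phi: float = 0.6
    period: int = 50
    noise_amplitude: float = 0.2236
    sign: int = 1
    missing_fraction: float = 0.0
    tie_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {MODELS}")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if not -1.0 < self.phi < 1.0:
            raise ValueError("phi must satisfy |phi| < 1 for stationarity")
        if self.period < 2:
            raise ValueError("period must be >= 2")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")
        if self.sign not in (1, -1):
            raise ValueError("sign must be +1 or -1")
        for name in ("missing_fraction", "tie_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.model == "rotation_extremal" and self.length > 1000:
            raise ValueError(
                "rotation_extremal is limited to length <= 1000: the "
                "geometric values |base|^t leave double range beyond that"
            )


def generate(spec: SyntheticSpec) -> TimeSeries:
    """Generate the series described by ``spec`` (fully reproducible)."""
    rng = np.random.default_rng(spec.seed)
    T = spec.length
    t = np.arange(1, T + 1, dtype=np.float64)

    if spec.model == "white_noise":
        x = rng.uniform(0.0, 1.0, T)
    elif spec.model == "gaussian_ar1":
        innov = rng.standard_normal(_AR1_BURN_IN + T)
        x = np.empty(_AR1_BURN_IN + T)
        x[0] = innov[0] / np.sqrt(1.0 - spec.phi**2)  # stationary start
        for i in range(1, x.size):
            x[i] = spec.phi * x[i - 1] + innov[i]
        x = x[_AR1_BURN_IN:]
    elif spec.model == "noisy_sine":
        x = np.sin(2.0 * np.pi * t / spec.period)
        x += spec.noise_amplitude * rng.standard_normal(T)
    elif spec.model == "monotone":
        x = t.copy()
    elif spec.model == "alternating":
        x = (-1.0) ** t + 0.1 * rng.uniform(0.0, 1.0, T)
    elif spec.model == "updown_scaling_extremal":
        x = spec.sign * (t + (-1.0) ** t)
    elif spec.model == "rotation_extremal":
        base = -2.0 if spec.sign == 1 else -0.5
        x = base**t
    elif spec.model == "fixture_fig3":
        x = np.array(FIXTURE_FIG3)
    else:  # pragma: no cover - guarded in __post_init__
        raise AssertionError(spec.model)

    if spec.tie_fraction > 0.0 and T > 1:
        k = int(round(spec.tie_fraction * T))
        idx = rng.choice(np.arange(1, T), size=min(k, T - 1), replace=False)
        x[idx] = x[idx - 1]
    if spec.missing_fraction > 0.0:
        k = int(round(spec.missing_fraction * T))
        idx = rng.choice(T, size=k, replace=False)
        x[idx] = MISSING

    return TimeSeries(x)
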