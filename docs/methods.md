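# Methods

## Pattern counting

All statistics derive from tallies of order patterns of length three at
a lag d: the triple (x_t, x_{t+d}, x_{t+2d}) is classified by its rank
word (digit i = rank of the i-th value, 1 = smallest; (0, 1, −1) ↦ 231),
with t running over 1 … T−2d. Pairs (x_t, x_{t+d}) are tallied over
t = 1 … T−d into ups (12) and downs (21). A triple or pair is skipped
when it contains a missing value or an exact tie; ties between the
first and third value of a triple count, even though those two values
are never adjacent. Length three is a deliberate restriction: six
patterns can be estimated reliably from a few hundred points, whereas
longer patterns need far more data and add little for multiscale
signals explored by varying d.

Conventions that matter:

- **Missing values** are IEEE NaN internally; the readers map
  configurable sentinels ("NA", "NaN", empty field) to NaN. A
  comparison with NaN is never an ordering — the pattern is undefined.
- **Ties are exact** (`==`). The patterns are combinatorial objects;
  an epsilon-band tie rule would introduce a scale-dependent knob and
  break invariance under monotone transforms, so none is offered.
- Pairs are tallied independently of triples: a time point whose
  triple is spoiled by a missing middle value still contributes its
  valid pair. An optional restricted mode tallies pairs only on the
  triple support, which makes the support identity
  n123 + n132 + n231 = n12 exact (used by the tests).
- The optimised counter is vectorised (two rank comparisons and a
  bincount); an independent sort-based Python loop serves as its
  oracle in the test suite.

## The statistics and the exact decomposition

With frequencies p_π(d) = n_π/n the package computes the up-down
balance β, persistence τ, rotational asymmetry γ, up-down scaling δ,
permutation entropy H (natural log by default, base 2 on request;
0·log 0 = 0), the distance to white noise Δ², the turning rate
TR = 2/3 − τ, and the residual ε = p132 + p231 − p213 − p312.

β is reported in **both estimator forms**: from pairs (p12 − p21) and
from triples (p123 − p321). The two differ by margin and exclusion
effects of order O(d/n) — on the built-in fixture they are 0 vs −1/5 at
lag 1 — and the triple form is the one entering the decomposition,
because the identity lives entirely in triple-frequency space:

    4Δ² = 3τ² + 2β² + γ² + δ² + ε².

ε vanishes for process probabilities under stationary increments but
not for finite-sample frequencies, so it is computed rather than
assumed zero; with ε retained the identity is algebraic (it only
requires Σp_π = 1) and holds to ~1e−16 on any tally. The relative
components τ̃ = 3τ²/4Δ², β̃ = β²/2Δ², γ̃ = γ²/4Δ², δ̃ = δ²/4Δ² then sum
to 1 − ε²/4Δ². At Δ² = 0 the attribution is undefined and reported as
NaN, not as zero.

The scale identity δ(d) = β(2d) − β(d) is exact when both β values are
taken from the lag-d triple tally itself — β(2d) from the first-versus-
third comparison, β(d) as p123 − p321 — and holds up to an O(d/n)
margin error for independently estimated profiles. Both versions are
exercised in the tests.

Symmetries (verified by brute force on random gappy series): time
reversal preserves τ, Δ², H, TR and flips β, γ, δ; negation preserves
τ and γ and flips β and δ; the combined rotation flips only γ. Note
that the lagged-copy correlations ρ and Spearman are invariant under
negation, and equal +1 for any monotone series — increasing or
decreasing — since a trend makes the series and its shifted copy move
together; only β carries the direction of a trend. For the geometric
series x_t = (−2)^t the sign convention used here yields γ = +1 (and
γ = −1 for (−1/2)^t); the tests pin down |γ| = 1, the magnitude being
the convention-free statement.

## Comparison functions

Classical autocorrelation is implemented as the Pearson correlation of
(x_t, x_{t+d}) over complete pairs (pairwise deletion, no imputation),
Spearman likewise on mid-ranks of the complete pairs. Lags with fewer
than two complete pairs, or zero variance in either margin, are NaN.

## Sliding windows and the noise mask

Long recordings are sliced either into fixed windows (length and step
in samples; a trailing partial window is dropped rather than padded,
since within-window stationarity is the premise) or at positive-to-
negative zero crossings (x_t > 0, x_{t+1} ≤ 0), which aligns window
boundaries with the signal's own cycle and removes margin artefacts
for oscillating data. Any statistic is then assembled into a
(lag × window) matrix.

A cell is masked as noise-like when T·Δ² < 15, with T the **window
length in samples**. When ties or gaps thin out the valid triples the
effective sample size is smaller; the per-cell triple count n is
stored in the matrix so users can apply n·Δ² < threshold instead. The
threshold 15 is the package default and freely adjustable; raising it
can only mask more cells (monotonicity is tested). Undefined cells
(no valid triple) are always masked.

## Synthetic signals

The generator provides the study conditions for every test, fully
reproducible from (spec, seed):

- `white_noise`: iid Uniform(0,1) — continuous, so ties have
  probability zero; any continuous distribution gives identical
  pattern statistics.
- `gaussian_ar1`: x_{t+1} = φx_t + ε_t, standard normal innovations,
  a stationary start and 1000 burn-in samples discarded; the simplest
  reversible Gaussian process (default φ = 0.6), for which β, γ, δ
  vanish at every lag.
- `noisy_sine`: sin(2πt/L) + σ·N(0,1) with default σ = 0.2236
  (≈ √0.05), putting the noise power at one tenth of the sine's —
  enough noise to keep every pattern defined and to produce the
  characteristic bumped maximum of τ at the period.
- `monotone`, `alternating` ((−1)^t + 0.1·U(0,1) jitter to avoid
  ties), `updown_scaling_extremal` (±(t + (−1)^t)) and
  `rotation_extremal` ((−2)^t or (−1/2)^t) are the extremal series on
  which β, τ, δ, γ attain the boundary of their ranges. The geometric
  series is capped at T ≤ 1000 because |2|^t leaves double range.
- `fixture_fig3`: the ten-point worked example
  [4, NaN, 7, 9, 5, 8, 6, 2, 5, 5] with a missing x2 and the tie
  x5 = x9 = x10. This concrete series is a synthetic reconstruction
  built to satisfy all the published tallies of the worked example
  (p312(1) = 2/5; n12 = n21 = 3 at d = 1; n12 = 3, n21 = 4 at d = 2;
  both β estimators at both lags); it is the canonical fixture.

Injected gaps (`missing_fraction`) and ties (`tie_fraction`, copying a
neighbour's value) emulate sensor dropouts and quantisation. What the
generator does **not** emulate: heavy-tailed noise, regime switches,
nonstationary trends, correlated gap clusters, and measurement
quantisation of real instruments. Passing tests therefore demonstrate
correctness of the estimators and their exact identities under
controlled conditions, not performance claims on any particular real
recording.

## Problem sizes and tolerances

The exact identities (decomposition residual, TR = 2/3 − τ) are
asserted at 1e−12; they hold at ~1e−16 and the slack only absorbs
accumulation over extreme tallies. Calibration checks use T = 10⁶
white noise (binomial standard error ≈ 4·10⁻⁴ per frequency, asserted
within 0.002), the reversibility null uses an AR(1) of T = 10⁵ with
the odd functions bounded by 4/√T, and periodicity checks use a
T = 30 000 noisy sine with period 50. Decomposition exactness is swept
over hundreds of random gappy series of length 50–500 at every lag
with a defined triple. These sizes give fluctuation margins several
standard errors wide while keeping the whole suite under a minute.

## Known limitations

- Patterns of length three only; no multivariate or length-m ≥ 4
  patterns.
- No confidence intervals or hypothesis tests for the correlation
  functions; the noise mask's threshold is a practical default, not a
  calibrated p-value machinery.
- The closed form linking τ to ρ for Gaussian processes is not
  included; the AR(1) tests use simulation instead.
- WAV input is PCM integer or float, mono or first channel; no EDF or
  other physiological container formats.
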