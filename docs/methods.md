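# Methods

This note documents the models, conventions and design choices behind
`codtrends`, and what the synthetic-data tests do and do not demonstrate.

## Maturity ogive estimation

Individual maturity-at-length observations are modelled as independent
Bernoulli draws with logit p(L) = α + β·L. The fitter maximises the
Bernoulli log-likelihood by Newton iteration (equivalently iteratively
reweighted least squares) with step-halving to guarantee ascent;
convergence is declared when successive log-likelihood changes fall below
1e-10, with a cap of 100 iterations. Quasi-separation — the characteristic
divergence of |β| or its standard error when the two maturity classes do
not overlap in length — is detected (|β| > 1e3 during iteration, or
se(β) > 1e3 afterwards) and reported as non-convergence rather than as a
spurious estimate. Wald p-values come from the observed information matrix;
L50 = −α/β carries a delta-method standard error
Var(L50) = g'Σg with g = (−1/β, α/β²).

Acceptance of a fit requires convergence, a rising ogive (β > 0) and — by
default — *both* Wald p-values below 0.05. The plural reading ("both
parameters") is the stricter of the two natural interpretations of a
p-value rule stated for "the estimated parameters"; a slope-only rule is
available (`acceptance="slope"`). A minimum of 20 observations per
(year, subdivision) fit, with both classes present, is required; this
threshold is a package choice (no standard value exists) and is
configurable. The annual L50 is the arithmetic mean of accepted
subdivision estimates; a year with no accepted fit is missing, never zero.

Maier-scale coding: stages 1–2 immature, 3–7 mature; ranges collapse to
their lowest endpoint *before* coding; unparseable tokens are excluded with
a logged warning. Stage 8 (spent) is excluded by default — the binary
coding convention covers only 1–7, and excluding is conservative — but can
be retained, in which case a spent fish counts as mature (it has spawned).
Ogive data are restricted to April–August (inclusive) and, by default, to
subdivisions 25–29; sexes are combined (a per-sex fit is a caller-side
filter away, as sex is carried through).

## Condition and size-structure indicators

* Fulton's CF = 100·W/L³ (W in g, L in cm). Annual values average per-(year,
  SD) means over 41 ≤ L ≤ 60 cm, computed only when the cell holds strictly
  more than 5 records, then average across subdivisions — mirroring the L50
  aggregation.
* The length–weight relationship W = a·L^b is fitted by OLS on natural
  logs over 20 ≤ L ≤ 100 cm, pooled across years. LeCren's
  K_i = W_i/(a·L_i^b) follows; because OLS residuals on the log scale sum
  to zero, the geometric mean of K over the fitting sample is exactly 1 —
  a property the tests assert to 1e-10.
* LDI is the Shannon–Wiener entropy (natural log) of the pooled annual
  1-cm length-frequency distribution over classes ≥ 20 cm, with 0·ln 0 := 0.
  Pooling all hauls with raw counts as weights is the default; this matches
  treating the annual survey catch as one distribution.
* L95 is the 95th percentile of lengths ≥ 20 cm using linear interpolation
  of order statistics, h = (n−1)·0.95 + 1 (the common statistical-software
  default; the convention is stated because published indicator series do
  not document theirs). Class-count input is expanded at class lower
  bounds. Length classes are integer lower bounds of half-open [LC, LC+1)
  bins throughout.
* CPR_i = Catch_i·10⁶/REC_{i−4} (catch in tonnes, recruits in individuals,
  so CPR is in grams per recruit); the 4-year lag reflects the mid-point of
  the yield curve of a cohort. Z46 = F46 + M46 with the conventional
  M46 = 0.2/yr substituted when M46 is missing for a year before 1991;
  ER = F46/Z46, undefined at Z46 = 0. These are exact arithmetic on their
  inputs.

The spawning-window filter applies only to ogive estimation; LDI and L95
use all survey records, reflecting the different record sources feeding
each indicator.

## Trend inference

`mk_statistics` returns the Kendall score S, its tie-corrected variance
Var(S) = [n(n−1)(2n+5) − Σ t(t−1)(2t+5)]/18, the continuity-corrected
deviate Z = (S∓1)/√Var(S) (0 at S = 0) and Kendall's tau-b (time points are
untied, values may tie). Missing years are dropped; pairs form on time
order, so gap years are handled naturally. Sen's slope is the median of
all pairwise slopes over calendar-year spacing.

The bootstrap null resamples contiguous *non-overlapping* blocks with
replacement (the moving-block variant is a one-line change but the
non-overlapping flavour matches the established block-bootstrap
Mann–Kendall procedure); block length defaults to 3 years — longer blocks
would absorb dynamics of little population relevance — with 2000
replicates. The series is truncated to a multiple of the block length and
*both* the observed score and the replicate scores are computed on that
truncated sequence, so the comparison never mixes sample sizes; the full
series still provides the reported S, Var(S), Z, tau and Sen slope. The
two-sided p-value uses the add-one rule p = (1 + #{|S*| ≥ |S_obs|})/(B+1),
so p is never exactly zero. Missing years are dropped before blocking
(blocks form on the observed sequence).

Calibration, computed by the acceptance script rather than quoted: on
trend-free AR(1) series with lag-1 correlation 0.4 and n = 50, the
bootstrap test's empirical size at nominal 5% sits near 0.09 — mildly
anticonservative, because resampling breaks correlation *across* block
boundaries — while the unmodified normal-approximation test rejects at
roughly twice that rate. Under a 1 sd/year trend the bootstrap p falls
below 0.01 essentially always.

Spearman correlations use average ranks with the t-approximation p-value
(the standard default; exact permutation p would only matter below n ≈ 10);
a perfect monotone pair reports p at the smallest positive float, never 0.
Pairs need at least 5 complete years; constant series are flagged as
zero-rank-variance rather than given a value. No multiple-testing
correction is applied to the correlation matrix, by design.

## Synthetic-data generator

The generator emulates the three record types with a known ground truth:

* **Age structure**: exponential survival at total mortality z (default
  0.5/yr) truncated at 15 years — the simplest structure consistent with a
  von Bertalanffy population under constant total mortality.
* **Growth**: L(t) = L∞(1 − e^(−K(t−t0))) with illustrative defaults
  L∞ = 110 cm, K = 0.15/yr, t0 = −0.5 yr. These are plausible for a large
  gadoid but are *not* stock estimates; any real application must supply
  its own.
* **Lengths** are recorded at 0.1 cm resolution after Gaussian measurement
  noise (default sd 0.5 cm) and floored at 1 cm.
* **Maturity** is Bernoulli on the logistic ogive evaluated at the
  *recorded* length (true L50 = 40 cm, width 8 cm between the 25% and 75%
  points, i.e. β = 2·ln 3/width), so the downstream logistic model is
  correctly specified and recovery tests measure estimator error, not
  model misspecification. The binary outcome maps to a uniform Maier stage
  of the matching group ({1,2} or {3..7}); 10% of stages render as ranges
  ("2-3") to exercise range coding.
* **Weights** derive from the recorded length as W = a·L^b (defaults
  a = 0.01 g·cm⁻³, b = 3) times lognormal condition noise (sd 0.1 on the
  log scale); with the noise at 0 the power law holds exactly, which is
  what lets the length–weight fit recover (a, b) to machine precision.
* **Catch records** bin simulated lengths by floor into 1-cm classes, one
  haul per (year, SD), so class counts conserve the haul total exactly.
* **Assessment/forage series** are stationary AR(1) processes (φ = 0.4)
  around fixed levels, exponentiated to stay positive; recruitment defaults
  to 5·10⁸ age-0 individuals so catch-per-recruit lands on the
  grams-per-recruit scale typical of assessment output. The AR(1) generator
  uses stationary initialisation e₀ ~ N(0, σ²/(1−φ²)).
* **Secular change** is modelled by linear per-year interpolation of true
  L50 (and optionally L∞) between start and end values.

Randomness: a single root seed feeds numpy `SeedSequence` children with
fixed stream indices per operation, generator PCG64 — outputs are
bit-reproducible across runs and platforms.

What the generator does *not* emulate: gear/mesh selectivity and its
change over time, spatial structure within subdivisions, sex dimorphism in
growth or maturation, density-dependent growth, and non-stationary
autocorrelation. Passing recovery tests therefore show that the estimators
are correct under a well-specified sampling model, not that archival
records are free of selectivity or digitisation bias — the latter is
explicitly out of reach without the original data.

## Problem sizes

The test-suite and acceptance-script experiments use 200 replicate
datasets of 2000 fish for ogive recovery; 500 simulated AR(1) series with
500 bootstrap replicates each for test size (and 100 seeds for power,
where 500 replicates put the attainable p floor at 1/501 < 0.01); and a
60-year, 5-subdivision, 600-fish/yr stock with 2000 replicates for the
end-to-end run. These sizes give Monte-Carlo standard errors comfortably
inside the asserted bands.

## Degenerate inputs and tie-breaks

Single-class maturity samples, too-few records, separated data and falling
ogives all return explicit no-fit/rejected results with reasons, never
exceptions mid-pipeline; empty year ranges warn and return empty frames;
zero recruits, Z = 0 and below-minimum-length-only years propagate as
missing values; all-tied series return S = 0, Z = 0, tau = 0 flagged
"all tied". Records are never silently dropped: every reader returns a
rejects list with line numbers, every filter is order-preserving and
idempotent, and the run summary reconciles records in = used + removed at
each stage.
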