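# Methods

`cogspan` models cross-sectional cognitive aging: how composite scores in
three cognitive domains — working memory (WM), verbal ability and
reasoning — rise and decline with age, separately for women and men, and
whether the two sexes differ in when and how fast.

## The trajectory model

For one sex and one domain, the score of participant *i* at age *x_i* is

    y_i = a + b x_i + Σ_k δ_k (x_i − ψ_k)_+ + ε_i,    ε_i ~ N(0, σ²),

a continuous piecewise-linear ("broken-line" or segmented) mean with
breakpoints ψ_1 < … < ψ_K. Segment slopes are the cumulative sums
b, b + δ_1, …; δ_k is the change in the age coefficient after ψ_k. The
model imposes no global shape (no quadratic/cubic curvature), so a peak is
represented as a breakpoint where the slope changes sign, and the number
of regime changes K is itself estimated.

### Estimation

`fit_segmented` uses iterative linearisation: at working values ψ, the
model augmented with the gap terms −γ_k·1{x > ψ_k} is linear in its
coefficients; OLS gives (γ̂, δ̂) and the update ψ_k ← ψ_k + γ̂_k/δ̂_k. At a
fixed point γ̂ = 0 and the fitted line is continuous. Implementation
choices that the broken-line literature leaves open are fixed as follows:

- **Initialisation.** When no starting values are supplied, a coarse
  profile-least-squares search over a quantile grid (30 candidates for
  K = 1, all admissible pairs/triples of a 12–14 point grid for K = 2, 3)
  selects the start. The update is only locally convergent; starting in
  the right basin matters far more than the update itself.
- **Damping.** Each update is step-halved until the profile RSS does not
  increase, which prevents the oscillation the raw update exhibits on
  noisy data.
- **Polish.** After convergence each ψ_k is refined by a bounded scalar
  minimisation of the profile RSS (±5% of the admissible span,
  tolerance 1e−7). One-breakpoint fits then agree with an exhaustive
  dense-grid profile search to numerical precision (a tested guarantee).
- **Constraints.** ψ is confined to the 5th–95th percentile window of the
  observed ages with a minimum mutual separation of 2% of the age range;
  colliding breakpoints trigger a refit with K − 1 and a warning.
- **Convergence.** max|γ̂| < 1e−6 · SD(y), or a rejected/negligible step
  at the profile optimum; cap of 100 iterations, non-convergence is
  flagged, never silent.
- **Uncertainty.** SE(ψ_k) = SE(γ̂_k)/|δ̂_k| (delta method) from the final
  augmented OLS; segment-slope SEs come from the corresponding linear
  combination of the coefficient covariance. These Wald intervals are
  known to be slightly anti-conservative when the slope change is small
  relative to the noise; between-sex inference therefore uses the
  bootstrap instead (below).

### Model size selection and the slope-change test

`select_n_breakpoints` fits K = 0…3 and keeps the fit minimising
BIC = −2 log L + p log n under the Gaussian likelihood, with
p = 2 + 2K + 1 free parameters (intercept, base slope, and per breakpoint
one slope change and one location, plus σ²). Counting ψ as a free
parameter is deliberate; it is the stricter convention. Candidates that
fail to converge or collapse to fewer breakpoints are excluded.

`davies_test` addresses the non-standard null (ψ exists only under the
alternative): the Wald t statistic for a single added hinge term is
evaluated at 10 candidate locations evenly spaced between the 10th and
90th age percentiles, M = max|t_k|, and the p-value is the upper bound
2Φ(−M) + V e^{−M²/2}/√(8π) with V the total variation of the t sequence.
The bound is conservative; its empirical null rejection rate at α = 0.05
is ~2–5% (tested).

### Peaks and side slopes

The peak is the age of maximal fitted score among the window endpoints
and all ψ̂. A peak at a breakpoint carries that index; a peak at the
window edge is flagged `at_boundary` (an all-declining domain "peaks" at
age 12, which is then read as the age decline begins rather than a true
maximum). The summary slope on one side of the peak is the segment's
slope when one segment flanks it, and otherwise the length-weighted
average of the flanking segments — identically the chord slope of the
fitted line between the peak and the window edge, a property that is
tested exactly. Reported combined slopes from multi-segment sides are not
in general recoverable from the individual printed segment slopes without
the segment lengths; the chord definition is the one this package
commits to. If the peak sits at the boundary, the empty side's slope is
explicitly undefined rather than zero.

## Bootstrap comparison of the sexes

Between-sex differences in peak age, peak score and the two side slopes
are summarised by percentile bootstrap intervals: each replicate
resamples participants with replacement within sex, refits both sexes
with the full-sample breakpoint count held fixed (initialised at the
full-sample ψ̂), and records the women-minus-men difference; the 2.5% and
97.5% quantiles bound the interval, and an interval excluding zero is
read as a significant difference. No p-values are attached. Choices:

- **K held fixed per replicate.** Re-selecting K inside the bootstrap
  would mix model-selection variability into the parameter uncertainty;
  a config switch (`reselect_breakpoints`) restores the other behaviour.
- **Unequal pools.** When one sex's pool is larger (unmatched mode), the
  larger pool is subsampled without replacement to the smaller size each
  replicate (`subsample_male_n`), equalising effective information.
- **Seeds.** Replicate RNGs are derived counter-style from
  (master seed, domain index, replicate index), so results are identical
  under any execution order or parallel arrangement.
- **Failures.** A replicate whose refit fails is dropped and counted;
  >5% failures raises a warning, >50% an error. A parameter undefined in
  a replicate (e.g. no increasing segment) contributes no draw.
- **B.** The analysis default is 10,000 replications; the shipped tests
  and the acceptance script use B = 500, at which the 2.5%/97.5%
  quantiles are stable to the precision reported.

## Cohort processing

**Exclusion cascade** (order fixed, each stage audited by a
`FilterReport`): (1) completeness — participants missing any test score
or questionnaire item are dropped; (2) two-pass outlier screen on the
test scores — any score more than 6 sample SDs from its column mean
(technical errors), then, after recomputing each column's moments on the
survivors, more than 4 SDs from the recalculated mean (performance
outliers); (3) closed age window [12, 69]. Removal is by whole
participant (composites need all 12 tests), distances use the (n−1)-SD,
and "greater than k SD" is strict. The screen is intentionally not
idempotent: an extreme value can mask a lesser one by inflating the SD,
which is exactly what the recalculation between passes addresses (tested
on a worked masking example).

**Composite scores.** Test scores are z-scored over the sample being
analysed (after matching, when matching is used) and projected onto the
three domains with Y = X (Ar⁺)ᵀ, where Ar is the 12×3 varimax-rotated
component weight matrix and Ar⁺ its Moore–Penrose pseudo-inverse; row-wise
this is the least-squares domain triple that best reconstructs the
participant's test profile, and every test informs every domain. A
published weight matrix is accepted as input (12×3 CSV); `derive_weights`
re-derives one from data (PCA loadings of the correlation structure,
varimax with Kaiser row-normalisation, tolerance 1e−8; column order fixed
by explained variance, sign by making the largest loading positive).

**Demographic battery.** Women vs men on each covariate with the
type-appropriate test — Welch's t (continuous; Cohen's d with classical
pooled SD), Wilcoxon rank-sum (ordinal; midranks, tie-corrected variance,
continuity correction, exact enumeration for n ≤ 10; effect r = |z|/√N),
Pearson χ² without continuity correction (categorical; Cramér's V) —
with Benjamini–Hochberg FDR applied jointly and significance declared at
adjusted p < 0.01. Variable typing is caller-supplied, not inferred (a
table may legitimately treat an orderable variable as categorical). Sign
convention: women minus men, everywhere. Welch is also computable from
summary statistics for published-table checks.

**Matching.** Propensity = fitted probability of membership in the
smaller sex group, from a Newton/IRLS logistic regression (tol 1e−8,
max 100 iterations; constant design columns dropped with a warning;
perfect separation is an error). Greedy 1:1 nearest-neighbour matching
without replacement: treated units in descending propensity order, each
paired to the closest unused control, all ties broken by lowest
participant id — fully deterministic. No caliper and no exact-matching
constraints. Balance is reported as standardised mean differences
(continuous/ordinal) or maximum level-proportion differences
(categorical), before vs after.

## The synthetic generator

`generate_cohort` emulates the statistical structure the analysis
assumes, so that every stage is testable without any data download:

- **Ages** from a truncated normal on [12, 69] calibrated to mean 28.2
  and SD 10.8 years — the demographic profile of a young-skewed online
  cohort. This choice also keeps the population mean of each domain
  trajectory near zero, so the z-centred composite scores sit on the
  scale the trajectory parameters are stated on. A uniform density is
  available (`age_dist="uniform"`).
- **Trajectories**: sex-specific piecewise-linear domain means; the
  defaults are the matched-sample estimates (WM peaking at 20.4/19.7
  years with rise ~+0.04 and decline ~−0.02 SD/yr; verbal rising steeply
  to ~16.5/17.2, slowly to a peak at 24.9/28.4, then declining gently;
  reasoning declining from age 12 in women with a steeper phase after 38,
  and plateauing to ~19.6 before declining in men).
- **Test scores**: mean of test j is Σ_d Ar[j,d]·domain_d(age) plus
  independent Gaussian noise (default SD 1 per test). Mixing through the
  same weight matrix the scorer inverts makes `compute_domain_scores`
  approximately invert the generator, enabling end-to-end recovery tests.
- **Covariates** with calibrated sex effects: continuous shifts of
  ±d·σ/2; ordinal variables by thresholding a shifted latent normal, the
  shift solving (θ−½)√(3/tf) = r with θ the win probability and tf the
  tie factor 1−Σp̄³ (the asymptotic rank-shift identity); categorical
  variables by exponential tilting of the level probabilities, the tilt
  solving the population Cramér's V identity V² = Σ_j Δ_j²/(4 p̄_j).
  Defaults: sleep d = +0.10, caffeine d = −0.19, anxiety r = +0.15, tech
  savviness V = 0.24, education and exercise null.
- **Contamination**: a configurable fraction of participants gets one
  missing item (default studies use 13.7%); a configurable fraction of
  score cells is replaced by values ±7 SD from the column mean
  (`inject_outliers`, which also returns the altered cell index so tests
  can verify the screen removes them).

What the generator does **not** emulate: item-level responses or response
times, the true (unknown) empirical age density, non-Gaussian score
distributions, cohort effects, and correlations between covariates and
cognitive scores (covariates affect matching and the demographic battery
but are generated independently of the test scores). Passing tests
therefore demonstrate that the statistical machinery recovers known
structure under the model's own assumptions — not that those assumptions
hold in any particular real cohort.

A known, intended consequence of scoring: z-scoring divides each test by
its total SD (signal + noise), so recovered slopes are attenuated a few
percent toward zero relative to the generating trajectories, and absolute
fitted scores are centred on the cohort mean (offsetting them by up to
~0.1 from the generating values when the age density and trajectories
leave a nonzero population mean). Between-sex differences are unaffected,
because both sexes share the centring.

## Problem sizes and numerical conventions

Validation uses study-scale cohorts of 13,444 per sex (the size of the
smaller unmatched pool) for recovery, selection and calibration checks
(200, 50 and 1,000 replicates respectively), and smaller cohorts
(1,000–6,000 per sex) with B = 500 for bootstrap coverage, sizes chosen
to keep the full suite a few minutes long while leaving Monte-Carlo error
well inside the asserted bands. Degenerate inputs have defined behaviour
throughout: zero-variance score columns are skipped by the outlier screen
(warning) and rejected by z-scoring (error naming the test); two
zero-variance samples with equal means give t = 0, with unequal means an
error; fully tied rank-sum data give p = 1; a perfect linear fit makes
Davies' test return p = 1 with a note; B = 1 collapses a bootstrap CI to
a point.

## Limitations

Cross-sectional trajectories confound age with cohort; nothing here
corrects for that. The delta-method ψ intervals are mildly
anti-conservative at low signal-to-noise (measured coverage ≈ 0.90 at the
default study scale). BIC occasionally under-selects a weak second
breakpoint near the boundary of detectability, which can move a reported
peak age considerably — a real instability of breakpoint-count selection,
visible in this package's outputs exactly as it is in the analyses it
re-implements. Matching quality depends on pool imbalance: with equal
pools, 1:1 matching without replacement pairs everyone and removes no
imbalance.
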