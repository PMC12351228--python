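# Methods

## Scope and design

The package implements a complete short-form development procedure for the
36-item CPM as five cooperating parts: a calibrated item-response
simulator, an elastic-net solver, the development pipeline (splitting, grid
search, stopping rule), the validation battery, and I/O/CLI plumbing.
Everything downstream of the simulator is data-agnostic: any persons ×
items binary matrix with the CPM column layout can be substituted for a
synthetic cohort.

## Response model and calibration

Responses follow a unidimensional two-parameter logistic (2PL) model:
person ability θ ~ N(0,1); item j has discrimination a_j > 0 and difficulty
b_j (logit scale); P(correct) = logistic(a_j(θ − b_j)), independent across
items given θ. The 2PL is the minimal structure that can reproduce both a
fixed vector of marginal proportions correct and a tunable internal
consistency; no claim is made that real CPM data are exactly 2PL (see
Limitations).

Difficulties are calibrated so that the *marginal* proportion correct,
E_θ[logistic(a(θ − b))] evaluated by 61-node Gauss–Hermite quadrature,
equals each item's published whole-sample proportion (range .09–.99 across
the 36 items). The marginal is strictly decreasing in b, so each difficulty
is found by bracketed root-finding; the bracket widens as 1/a because weak
discriminations flatten the marginal. Calibration is exact to 1e−10 on the
quadrature marginal and verified by simulation to ±.01 at n = 100,000.

Discriminations are drawn log-normal(0, 0.25) per item — heterogeneity is
what gives the selection procedure signal to prefer some items — and then
scaled by one common factor until the full-form (34 scored items)
Cronbach's α on a 20,000-person fixed-seed probe sample is within ±.02 of a
target. The default target is .86, the published validation-set value; the
whole-sample value (.80) can be requested instead via
`CohortSpec(target_alpha=...)` — the two differ in the source study and the
choice is deliberately exposed rather than silently resolved. The probe
alpha is monotone in the factor, so geometric bisection over factors
[0.05, 8] converges in a handful of evaluations; difficulties are
re-calibrated at every factor so marginals stay on target. Practice items
A1/A2 are generated for format fidelity but flagged and excluded from all
scoring.

Covariates are built as ρ·θ + √(1−ρ²)·noise with target correlations to
ability of .44 (backwards digit span), .41 (HTKS), .50 (receptive
vocabulary) and −.14 (RAN inverse-efficiency), then mapped into instrument
ranges: bounded integer scores are centred at the range midpoint with
sd = range/6, rounded and clipped; the RAN inverse-efficiency score — a
positive time/accuracy ratio with a long right tail — gets a shifted
log-normal shape (floor 10, median ≈ 40). The affine map is lossless for
the correlation; rounding/clipping attenuates it by well under the
tolerances used anywhere. Missingness is completely at random with rates
0/.09/.26/.29, chosen so a 101-person validation split yields pairwise ns
near the published 101/92/75/72. One master seed governs everything;
per-stage child streams are derived from fixed labels so each stage is
independently reproducible.

What the generator does *not* emulate: learning across items within a
session, multidimensionality or testlet effects, differential item
functioning, age trends, and any non-MCAR missingness mechanism. Passing
tests therefore demonstrate that the pipeline recovers the right answers
when its assumptions hold, not that those assumptions hold for real
cohorts.

## Elastic-net solver

The solver minimises (1/2n)‖y − β₀ − Xβ‖² + λ(α‖β‖₁ + (1−α)/2‖β‖₂²) by
cyclic coordinate descent with soft-thresholding, using precomputed Gram
products so a sweep costs O(p²) independent of n. Predictors are
standardised internally (population sd); the response is left on its raw
0–34 scale so that the λ ∈ [1, 3] grid retains its meaning (λ_max for
these data is ≈ 3–4); coefficients are reported unstandardised and the
intercept is unpenalised. Convergence is declared when the largest
standardised-coefficient change in a sweep falls below 1e−7 (max 10,000
sweeps — problems are at most ~235 × 34). Coordinate order is cyclic in the
canonical A → Ab → B item order, so fits are deterministic without a seed.
Zero-variance predictors (items everyone in a small train split answers the
same way) are excluded from the fit with a warning and fixed at zero. The
support is read off at |β| > 1e−10; coordinate descent produces exact
zeros, the threshold only guards float dust. Tests verify the solver
against the OLS normal equations (λ = 0), the closed-form ridge solution
(α = 0), the univariate soft-threshold formula, the λ_max KKT bound, an
independent proximal-gradient (ISTA) minimiser, and scikit-learn's
implementation; the per-sweep objective is asserted non-increasing.

## Development pipeline

Splitting allocates floor(.35n)/floor(.35n)/floor(.30n) to
train/test/validation with the remainder going to validation first, then
test: at n = 336 this yields 117/118/101 with the development total 235.
The grid is α ∈ {.40, .45, …, 1.00} × λ ∈ {1.00, 1.05, …, 3.00} (every
published candidate's pair is a multiple of .05 inside those ranges);
within each α the λ path is walked from large to small with warm starts.
Identical supports arising at several grid points are deduplicated with
counts kept; each unique support is scored once on the test split by
unit-weighted sum (the short form is always scored as a plain sum, not by
the regression weights, since that is how short forms are administered).
Best-per-length selection breaks exact ties by larger λ, then smaller α,
then lexicographic item order — a deterministic preference for the more
parsimonious regularisation path. Per-length gains are computed from
unrounded correlations between consecutive *available* lengths (the search
does not produce every length).

The stopping rule is exposed in three readings because the <1% criterion
is genuinely ambiguous around a negative gain: `first_below` stops at the
first length whose gain to the next is below threshold (returns 7 on the
published sequence, because the 7→8 gain is −0.17%);
`first_below_skip_negative` treats an isolated negative gain — one whose
following gain is back above threshold — as an anomaly and skips it
(returns 10); `all_subsequent_below` picks the smallest length beyond which
every gain stays below threshold (returns 12, the published final choice,
and is the package default). Thresholds and gains are fractions internally
(0.01 = 1%); displays multiply by 100.

## Validation battery

Cronbach's α uses the standard variance decomposition on complete cases
with sample variances; values are never clamped (negative α is
informative). Correlations are pairwise-complete Pearson r, always carried
with their n. BCa bootstrap intervals (bias correction from the bootstrap
distribution's position of the point estimate, acceleration from jackknife
skewness) are delegated to `scipy.stats.bootstrap(method="BCa")` behind the
`bca_ci` surface, with B = 2,000 by default (the source procedure states
BCa but not B; 2,000 gives stable 95% quantiles at these n). Degenerate
bootstrap distributions collapse to the point estimate with a warning.
Coverage is verified at 92–97% for a normal mean (n = 50, 1,000
simulations).

The stability simulation re-halves the development set at random 100
times, reruns the full grid search, and tallies how often each item appears
in the best candidate of the target length; runs lacking that exact length
fall back to the nearest available length (preferring longer), recorded
per run. The random-subset baseline draws 100 uniform same-length subsets
on the validation split; exceedance is strict (ties do not count as
outperforming), and single-item subsets carry α = NaN since alpha is
undefined at k = 1. Content validity is a counting check against the CPM
manual's nine cognitive-demand domains (A1–A8, A9–A10, A11–A12, Ab1–Ab3,
Ab4–Ab12, B1–B2, B3–B5, B6–B9, B10–B12; full-form counts
8/2/2/3/9/2/3/4/3).

## Problem sizes and observed behaviour

The replication harness (`cpm_shortform.replication`) runs ten independent
seeds of the full path — tune, generate n = 336, develop over the full
13 × 41 grid, evaluate on the 101-person validation split with 100 random
12-item baselines — in well under a minute on one CPU. Across seeds the
stability-oriented stopping rule selects lengths of roughly 10–18 (the gain
sequence near 1% is noisy at this n), so the 12-item-specific metrics are
computed on the best 12-item grid candidate, which coincides with the
selected form whenever the rule lands on 12. Monte Carlo stability with the
full grid costs ~1–2 s per run (~2–3 min for 100 runs) and is switched on
in the CLI by default but exercised at reduced grids in the test suite.

## Known limitations

- The simulator's calibration targets are whole-sample proportions from
  one Hong Kong preschool cohort; nothing here produces age norms or IQ
  conversions.
- Sum-score equivalence between short and full form is assessed by
  correlation only; no equating or measurement-invariance analysis.
- The stopping rule's behaviour is sensitive to test-split noise at
  n ≈ 336; users with larger cohorts should expect more stable selected
  lengths.
- MCAR covariate missingness is a modelling convenience; real missingness
  in assessment batteries is rarely MCAR.
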