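# Methods

## Estimand and assumptions

Let `Y` be a connectivity outcome (one edge), `A ∈ {0,1}` diagnosis
(1 = ASD), `Δ ∈ {0,1}` scan usability after motion QC, and `W` the
phenotype block. The target is

ψ_a = E{ E(Y | A=a, Δ=1, W) | A=a },  and the group difference
ψ = ψ_1 − ψ_0.

The outer expectation runs over each diagnosis group's full covariate
distribution — usable and unusable participants — which distinguishes
ψ from the usable-case ("naive") contrast
E(Y | Δ=1, A=1) − E(Y | Δ=1, A=0). ψ identifies the group difference
of the counterfactual "all scans usable" world under:

1. *Mean exchangeability*: given `A` and `W`, usable-scan outcomes
   have the same mean as counterfactual all-usable outcomes — `W` must
   contain every variable jointly related to usability and
   connectivity;
2. *Positivity*: every phenotype profile has positive probability of
   passing QC;
3. *Consistency*: an observed usable outcome equals the counterfactual
   outcome.

This is deliberately *not* an average treatment effect: each group is
integrated over its own covariate distribution, not the pooled one.

## Estimators

Per diagnosis group, with propensity `g(A,W) = P(Δ=1|A,W)` and outcome
regression `Q(A,W) = E(Y|Δ=1,A,W)`:

- **AIPW**: ψ̂ = mean of `Δ/g·(Y−Q) + Q` over group rows; SE is the
  standard deviation of that integrand over √n. Consistent if either
  nuisance is.
- **TMLE**: one weighted-intercept fluctuation of Q (weights `Δ/g`)
  solves the efficient-influence-function equation exactly; ψ̂ is the
  mean fluctuated Q.
- **DRTMLE**: additionally estimates two reduced-dimension nuisances
  by univariate local-linear kernel regression —
  `Qr(g) = E[Y−Q | Δ=1, g]` and `gr(Q) = E[Δ | Q]` — and iterates
  (a) a logistic fluctuation of g along `Qr(g)/g` and (b) a weighted
  linear fluctuation of Q solving the estimating equations of the
  directions `1/g` and `(gr−g)/(g·gr)`. With these extra equations
  solved, the influence-function variance remains valid when one
  nuisance model is inconsistently estimated, not just the point
  estimate.

Numerical choices in DRTMLE:

- The Q-fluctuation is implemented in *weighted* form: the residual is
  regressed on the bounded directions `[1, (gr−g)/gr]` with weights
  `Δ/g`. This solves the same two equations as the covariate form but
  prevents the fluctuated Q from being extrapolated to extreme values
  on low-propensity unusable rows, which otherwise destabilizes the
  plug-in mean whenever Q is badly misspecified and the propensity has
  a thin tail.
- Convergence is declared when the empirical means of the efficient
  influence function and both extra correction terms fall below
  `1/(√n·log n)` — the sampling scale of the re-estimated
  nonparametric nuisances; a fixed tolerance far below that scale is
  unattainable and iterating toward it degrades the estimate. At most
  10 iterations; failure raises with the residual equation values.
- Propensities are truncated at 0.01 inside DRTMLE (10⁻³ elsewhere);
  clipped values trigger a positivity warning.
- The local-linear smoother uses a Gaussian kernel with bandwidth
  chosen by leave-one-out cross-validation over a small multiplicative
  grid around the `n^(-1/5)` reference rate (subsampled to ≤ 400
  points); a constant regressor falls back to the global mean, which
  makes the no-missingness case exact.

The naive comparator uses group means of usable cases with a
Welch-form SE. Group differences are compared with independent
z-statistics (negative z ⇔ ASD < TD), optionally averaged over
repeated cross-validation seeds, with Benjamini–Hochberg adjustment
across edges (default levels 0.2 and 0.05 both reported).

## Super learner

Both nuisances are fit by a from-scratch cross-validated stacking
ensemble: out-of-fold predictions for each library member (V = 10
folds by default; configurable, optionally stratified), then convex
weights minimizing cross-validated risk — squared error (continuous)
or negative Bernoulli log-likelihood (binary) — solved over the
probability simplex with SLSQP (tolerance 10⁻¹⁰, vertex polish), so
the ensemble's CV risk never exceeds any single member's. Learners are
refit on all data for prediction; binary ensemble probabilities are
clipped to [10⁻³, 1−10⁻³] to protect downstream inverse weighting.

The default library spans the algorithm families used in this problem
class: intercept-only, GLM, lasso (CV-penalized), an additive
cubic-spline model, a piecewise-linear spline basis with lasso
selection (the MARS family), forward-stepwise GLM by BIC with and
without pairwise interactions, random forest and gradient boosting —
plus ridge and support-vector regression for continuous outcomes. A
`fast=True` subset (mean, GLM, lasso, splines) is the default inside
the pipeline object and is what the simulation studies use; any
`(name, estimator)` list with the sklearn protocol can be substituted.
A learner that errors in CV or refit is dropped with a warning and the
weights are renormalized; the fit fails only if every learner fails.

## Motion QC and connectivity

Framewise displacement follows the Power convention: sum of absolute
frame-to-frame changes of three translations (mm) and three rotations
converted to arc length at a 50 mm radius; the first frame is 0.

- *Lenient rule*: a transition with > 3 mm translation or > 3°
  rotation on any single axis breaks the series; usable iff the
  longest unbroken segment spans ≥ 300 s. "Continuous" is read as the
  longest contiguous run; per-axis thresholds follow the common
  realignment-parameter convention (a combined-magnitude variant of
  the ambiguity is noted, not implemented).
- *Strict rule*: usable iff mean FD ≤ 0.2 mm **and** frames with
  FD ≤ 0.25 mm total ≥ 300 s. Boundary cases are usable (exclusion
  requires the mean to *exceed* 0.2 mm).
- Among multiple usable scans per participant, the one with minimal
  mean FD is selected.

Partial correlations among K component timecourses are computed as
`Θ = (R + ρI)⁻¹`, `p_ij = −θ_ij/√(θ_ii θ_jj)` with ρ = 1 by default;
the *correlation* matrix is regularized (scale invariance) rather than
the covariance. Signal-signal edges are Fisher z-transformed and
flattened in a fixed row-major lower-triangle order; the edge-index ↔
component-pair bijection is exposed by `edge_labels`.

Before group analysis each edge is adjusted by OLS on mean FD, max FD,
the count of frames with FD < 0.25 mm, sex (reference female), race
(reference African American, one-hot), SES and diagnosis (reference
Autism); the adjusted value is the residual plus the intercept and the
subject's own diagnosis term. This removes nuisance mean effects while
leaving the fitted diagnosis contrast — and hence the adjusted group
difference — intact. Note the adjusted difference equals the *raw*
difference only when the nuisance covariates are balanced across
groups; when they are not, moving it is the point of the adjustment.

## Selection-bias diagnostics

Exclusion probability (logit link) and mean FD (identity link) are
smoothed on each phenotype with a 10-dimensional cubic B-spline basis
penalized by the integrated squared second derivative; the penalty
weight is chosen by REML (Gaussian) or its PQL/working-model
approximation (binomial), optimized on the log scale. Term p-values
use a Wald statistic on the smooth block's leading eigen-directions:
for Gaussian smooths the test dof is the smoothing-uncertainty-
corrected `2·tr(F) − tr(FF′) − 1` with an F reference; for binomial
smooths the rounded effective dof with a χ² reference. Both choices
were selected by null-calibration simulation (p-values
indistinguishable from uniform at n ≈ 500) and the fitted curves agree
with an independent REML GAM implementation to
well under the noise scale on a fixed fixture.

Included-vs-excluded comparisons use one-sided Mann-Whitney U tests
(exact for small tie-free samples, tie-corrected normal otherwise)
with effect size `r = |Z|/√N`; the `Z/N` variant that sometimes
appears in print cannot produce effect sizes in the commonly reported
range and is not used. The exclusion-proportion test is a Pearson
chi-square with Yates continuity correction by default for 2×2 tables
(uncorrected variant available). BH adjustment is applied within
explicit families: 7 exclusion smooths, 7 mean-FD smooths, 13 rank
tests (7 ASD + 6 TD; ADOS is ASD-only, set to 0 for TD wherever it
enters a predictor block).

## Synthetic data

The **toy cohort** is the package's ground-truth instrument: ASD
prevalence 25%; severity `W_c` = 0 for TD and lognormal(log-mean 2,
log-sd 0.4) for ASD; nine standard-normal nuisance covariates;
usability `Δ ~ Bernoulli(expit(2 − 0.2·W_c))`; outcome
`Y = 1.4·A − 0.2·W_c + ε`, `ε ~ N(0, 0.2²)`. The residual sd 0.2 is
derived, not free: with the group-weighted pooled variance
`σ² + 0.25·(0.2)²·Var(lognormal)` it simultaneously yields a pooled
corr(W_c, Y) of −0.56 and a between-group Cohen's d of 0.51, and the
counterfactual means are 0 (TD) and 1.4 − 0.2·exp(2.08) ≈ −0.20
(ASD), with ≈ 88% / 60% usable data. `toy_truth` returns these by
closed form or quadrature; the generated table carries both the
δ-masked `Y` (missing as NaN, never 0) and the counterfactual
`Y_complete` for bias measurement.

The **developmental cohort** emulates a developmental sample end to end:
phenotype distributions shifted by diagnosis (ADOS ASD-only, SRS,
DuPaul inattention/hyperactivity, motor overflow, GAI, age,
handedness, secondary ADHD, stimulant use, sex, race, SES); motion
traces generated as Gaussian random walks plus sporadic transient
spikes whose log-amplitude rises with symptom severity and falls with
age and GAI; usability determined by actually running the QC rules on
those traces; and edge outcomes with linear diagnosis and phenotype
effects. Amplitude defaults were fixed once so the QC rules exclude
roughly 15% of TD and 27% of ASD scans (lenient) and the majority of
scans (strict) — the regime the method is meant for. The motion model
is a plausibility construction, not a fit to any dataset; its
parameters are documented in `CohortConfig`.

What the generators do **not** emulate: temporal autocorrelation and
physiological structure of real rs-fMRI, ICA estimation error,
site/scanner effects, missing phenotype values, and any real-data
effect sizes at specific edges. Passing tests therefore demonstrate
estimator correctness under the stated generative assumptions, not
performance claims about any particular cohort.

## Problem sizes used in the test suite

Simulation-based checks run at deliberately chosen scales: 10⁶-row
cohorts for moment checks against closed forms; 500 replicates at
n = 550 (the study-like size) for the bias-correction comparison; 200
and 100 replicates at n = 500 and 5000 for double robustness under
single-nuisance misspecification; 500 replicates at n = 2000 for CI
coverage (observed ≈ 93%, inside the expected 90–98% band given mild
small-sample anti-conservatism of influence-function intervals); and a
300-subject, 10-edge cohort with two disjoint 6-seed sets for
multiseed stability (averaged-z correlation > 0.95). The simulation
tests use compact correctly-specified libraries (GLM + intercept-only)
so that what is being measured is the estimator, not library tuning.

## Known limitations

- Predictors must be complete; participants with missing phenotypes
  are excluded upstream (no imputation).
- Inference is normal-theory per edge; no permutation or resampling
  alternative is provided.
- The DRTMLE reduced-dimension regressions are univariate local-linear
  smooths; with very small groups (< ~30 usable rows) the bandwidth
  selection is noisy and AIPW may be preferable.
- No effect-size (Cohen's d) analogue is defined under the
  counterfactual estimand.
- The lenient rule's rotation threshold is applied per axis; a
  combined-rotation variant would be slightly stricter.
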