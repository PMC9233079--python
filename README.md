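# deconfc

Doubly robust estimation of group differences in functional
connectivity when motion quality control throws data away
non-randomly.

## The problem

Resting-state fMRI studies of developmental conditions exclude scans
that fail head-motion quality control. In cohorts of autistic (ASD)
and typically developing (TD) children this loss is *selective*: the
children who move most tend to be younger and to have more severe
symptoms, and those same phenotypes are associated with functional
connectivity. A "complete usable cases" comparison therefore estimates
the group difference in a biased subpopulation — often attenuated
toward zero.

`deconfc` treats excluded scans as missing outcomes. Writing `Y` for
an edge's connectivity, `A` for diagnosis, `Δ` for scan usability and
`W` for the phenotype block, the target is the **deconfounded group
difference**

```
ψ = E{ E(Y | A=1, Δ=1, W) | A=1 } − E{ E(Y | A=0, Δ=1, W) | A=0 },
```

the contrast obtained by integrating the outcome regression over each
diagnosis group's *full* covariate distribution (usable and unusable
children alike). Under mean exchangeability, positivity and
consistency, ψ equals the group difference that would be observed if
every child had a usable scan.

Estimation is doubly robust: a super-learner propensity model
`g(A, W) = P(Δ=1 | A, W)`, a super-learner outcome model
`Q(A, W) = E(Y | Δ=1, A, W)`, and a targeted (DRTMLE) combination per
diagnosis group whose point estimate and influence-function variance
stay consistent if either nuisance model is wrong. AIPW and plain
TMLE combiners are available as alternatives, as is the naive
usable-case comparison. Edgewise z-statistics can be averaged over
repeated cross-validation seeds and screened with Benjamini–Hochberg
FDR.

The package also implements the surrounding machinery:

- **motion QC** — Power framewise displacement, a lenient rule
  (≥ 5 min of continuous data after breaking the series at > 3 mm /
  > 3° jumps) and a strict rule (mean FD ≤ 0.2 mm and ≥ 5 min of
  frames with FD ≤ 0.25 mm), best-scan selection;
- **connectivity** — ridge-regularized partial correlations
  `Θ = (R + ρI)⁻¹`, Fisher-z signal edges, and per-edge OLS
  adjustment for motion and sampling-design covariates;
- **diagnostics** — penalized-spline GAMs (REML smoothing) of
  exclusion probability and mean FD on phenotypes, one-sided
  Mann-Whitney included-vs-excluded comparisons with `r = |Z|/√N`
  effect sizes, and the exclusion-proportion chi-square;
- **synthetic data** — a toy cohort with closed-form truth and a
  synthetic developmental cohort (phenotypes, realignment traces, edge outcomes) for
  end-to-end exercises.

## Worked example

The toy generative model plants severe selection bias: severity `W_c`
is lognormal in the ASD group and zero in TD; usability follows
`logit P(Δ=1|W_c) = 2 − 0.2 W_c`; the outcome is `1.4·A − 0.2·W_c`
plus noise. High-severity children are both lower-connectivity and
more likely to be excluded, so the usable-case difference collapses
while the true difference is −0.20:

```python
from deconfc import (ToyParams, generate_toy_cohort, toy_truth,
                     DeconfoundedGroupDifference)

params = ToyParams(n=550, seed=7)
cohort = generate_toy_cohort(params)
truth = toy_truth(params)

model = DeconfoundedGroupDifference(estimator="drtmle", v=5, seed=0, n_seeds=5)
model.fit(cohort.drop(columns=["Y", "Y_complete"]), cohort["Y"].to_numpy())
res = model.results_.iloc[0]
```

prints (via the obvious format strings):

```
true difference      : -0.201
naive difference     : -0.015  (z = -0.26, p = 0.793)
deconfounded (DRTMLE): -0.194  (z = -3.45, p = 0.0006)
min propensity       : 0.13
```

The naive comparison misses the group difference entirely (p = 0.79);
the deconfounded estimate recovers it to within 0.01 and detects it at
p < 0.001. `model.results_` is a per-edge DataFrame with ψ̂ per group,
the difference, seed-averaged z, p, BH-adjusted q and significance
flags at the configured FDR levels; `model.diagnostics_` carries the
propensity range and cross-validated AUC for positivity and fit
checks.

A command-line interface wraps the same functions for shell use:

```sh
deconfc simulate toy --n 550 --seed 7 --out toy.csv
deconfc qc rp_*.txt --tr 2.5 --out qc.csv
deconfc deconfound subjects.csv edges.csv --estimator drtmle --seeds 200 --out edges_out.csv
```

## Layout

```
src/deconfc/
  synthetic.py     # toy + developmental-cohort generators, traces, timecourses
  motion.py        # framewise displacement, usability rules
  connectivity.py  # ridge partial correlations, edges, adjustment
  superlearner.py  # cross-validated stacking (classifier/regressor)
  deconfound.py    # AIPW / TMLE / DRTMLE, naive comparator, FDR
  diagnostics.py   # REML GAMs, rank tests, chi-square, report
  cli.py           # thin command-line wrappers
docs/methods.md    # model, assumptions, numerical choices, limits
```
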