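# Methods

`pdprog` models longitudinal cognitive decline in Parkinson's disease
(PD) cohorts: an ordinal cognitive status (no cognitive impairment,
NCI < mild cognitive impairment, MCI < PD dementia, PDD) observed at
irregular clinic visits, together with a ten-test neuropsychological
battery, demographic/clinical covariates, and genotype risk indicators
(GBA variant carrier, APOE ε4 carrier, MAPT H1 homozygote). This note
documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the tests demonstrate.

## Synthetic cohort generator

The generator emulates a *prevalent* PD cohort: subjects enrol years
after motor-symptom onset (baseline disease duration ~ Gamma(2, 4)
years, capped at 35), return at 1-year (p=0.70), 2-year (p=0.25), or
3-year (p=0.05) intervals, and are followed for 1–8 years; a
configurable fraction (default 0.38) contributes a single visit.

Status at each visit is drawn from a cumulative-logit
(proportional-odds) model with a subject random intercept:

    P(Y_iv <= k | b_i) = logistic(alpha_k - x_iv' beta* - b_i),
    b_i ~ N(0, sigma_b^2),

and PDD is made absorbing afterwards (clinical reverters are excluded
from the kind of cohort this emulates, so the simulation never produces
them). Default `beta*` uses the published per-covariate log-odds for
this population: 0.18/year of age, 0.15/year of disease duration, 2.92
for male sex, 2.72 for GBA carriage, 0.23 for APOE ε4, −0.21 for MAPT —
so parameter-recovery tests run at realistic effect sizes. `sigma_b`
defaults to 1.5; the status model's subject heterogeneity in such
cohorts is substantial but not directly reported, and recovery tests
work at any value.

Two calibration details matter:

- **Threshold dilation.** The `prevalence` target (default 0.25 / 0.55 /
  0.20, matching a 208/459/160 baseline split) describes the *marginal*
  first-visit distribution. Because the latent predictor has variance
  `s^2 = Var(x'beta*) + sigma_b^2`, the cut-points are dilated by the
  logistic-normal factor `sqrt(1 + s^2/2.89)` around the realized latent
  mean. When all effects and `sigma_b` are zero the dilation is exactly
  1 and the configured prevalence is recovered to binomial accuracy.
- **Null configurations.** LEDD and GDS-15 are generated with
  status-dependent means and test scores with status-group means
  (anchored to the published baseline table), so a fully null cohort for
  calibration checks requires zeroing `test_status_gap_scale`,
  `ledd_status_effect`, and `gds15_status_effect` along with `beta` and
  the genotype test effects. Even then, because dementia is absorbing,
  any covariate that tracks time (age, disease duration) retains real
  predictive signal; null-AUC checks therefore use time-invariant
  covariates only.

Test scores are linear in status-group means (direction: higher is
better for all tests except Trailmaking B−A), additive genotype effects,
a per-test subject random intercept (default SDs per test), and Gaussian
noise. Missingness is MCAR at a configurable rate (default 2% when
enabled) over test scores, LEDD, and GDS-15 only — never identifiers,
times, or status. What the generator does *not* emulate: informative
missingness, mortality/competing risks, visit-schedule dependence on
disease severity, learning/practice effects across visits, or
measurement floors and ceilings. Tests passing on this generator show
estimator correctness under the assumed model, not robustness to those
real-data violations.

## Imputation

A restricted Boltzmann machine with Gaussian visible units for
standardized continuous columns and Bernoulli visible units for binary
columns, trained by CD-1 contrastive divergence (default: 32 hidden
units, learning rate 0.01, 200 epochs, mini-batches of 64). Missing
cells contribute nothing to the gradient and are refreshed each epoch
from the model's mean-field reconstruction. Imputation clamps observed
cells and runs 50 Gibbs sweeps, averaging the mean-field visible means.
Rows are treated independently (no pooling across a subject's visits).
A deterministic column-median imputer is available so downstream stages
can be exercised without the RBM; on tables with strong inter-test
correlation the RBM's masked-cell RMSE beats the median baseline.

## Ordinal and linear mixed models

The status model is a proportional-odds cumulative logit with a single
subject-level Gaussian random intercept, fitted by maximum marginal
likelihood. The intractable integral over the random effect is computed
by non-adaptive Gauss–Hermite quadrature (default 21 nodes — the
marginal log-likelihood changes by <1e-3 relative between 21 and 41
nodes on the fixtures here); the optimizer is BFGS on internally
standardized covariates with thresholds parametrized as
(alpha_1, log gap) and the random-intercept SD as log sigma_b.
Standard errors come from the finite-difference Hessian at the optimum,
transformed back to the raw covariate scale; Wald z and two-sided p
values are reported per coefficient, with OR = exp(beta) and 95% CI
exp(beta ± 1.96 se). A non-positive-definite Hessian (e.g. separation)
falls back to a pseudo-inverse and flags the fit. Predictions for
unseen subjects set the random intercept to its population mean of 0.

Test-performance models are random-intercept linear mixed models fitted
by ML (statsmodels MixedLM under this module's interface), one per test,
with genotype effects reported alongside Bonferroni-corrected p values
(`p_c = min(1, m p)`, m = number of tests analysed, 10 by default).

## Temporal grouped LASSO multitask model

Six binary logistic tasks predict status at horizons 0–5 years after
the first visit from first-visit features (horizon *n* uses the visit
whose time since the first visit is nearest to *n* within ±0.5 year).
Tasks share a weight matrix `W (d × t)` minimizing

    sum_i sum_j log(1 + exp(-Y_ij (W_i'X_ij + c_i)))
      + theta1 ||W||_F^2 + theta2 ||W H||_F^2 + theta3 ||W||_{2,1}

with `H` the first-difference matrix between adjacent horizons (smooth
progression through MCI) and the l2,1 row norm selecting features
jointly across horizons. The solver is FISTA with backtracking line
search on the smooth part and exact row-wise group soft-thresholding
for the l2,1 term; a monotone restart guards against momentum-induced
objective increases, and convergence is declared at relative objective
change < 1e-8. Rows whose norm ties the threshold map to the zero row,
so selected supports are exactly sparse. The ordinal extension fits one
model for P(NCI) and one for P(PDD); P(MCI) = 1 − P(NCI) − P(PDD),
clipped to [0, 1] and renormalized when the subtraction leaves the
simplex (reports flag when clipping fires). Features are z-scored on
training data only; weights are reported on the standardized scale.
Horizon 0 (same-visit status) is included, giving t = 6.

## Cross-validated evaluation

The outer layer repeats (default 100×) a 75/25 *subject-level* split —
splitting rows would leak within-subject correlation — and the inner
layer is a k-fold (default 5) grid search over (theta1, theta2, theta3)
on log-spaced candidates, scored by mean one-vs-rest AUC. AUC uses the
Mann–Whitney form with half-credit ties; single-class label sets are
excluded from aggregation and a split failing to retain all classes is
resampled (up to 20 times). The final multitask model averages the
outer-iteration weight matrices; mixed models are refit on the full
data. Per class (and per horizon) the report carries mean, SD, and
quartiles across outer iterations.

## Survival analyses

The endpoint is the first visit with a PDD diagnosis; subjects already
demented at their first visit are excluded and counted. Three time
scales are supported: years since motor onset, age, and months since
first visit. On the onset and age scales entry is delayed (left
truncation) because the cohort is prevalent — subjects join the risk set
only at enrolment; the months scale has entry 0 by construction. Event
times are taken at the diagnosing visit (no interval-censoring
adjustment). Kaplan–Meier, the multi-group log-rank test (hypergeometric
variance, chi-square with g−1 df), and the Cox partial likelihood with
Breslow tie handling are computed on explicit risk tables honouring the
entry times. The frailty option adds a shared log-normal random effect
per cluster via penalized partial likelihood, with the frailty variance
chosen by a Laplace-approximate profile likelihood over a bounded log
grid; variance 0 (or an all-singleton clustering, the
baseline-covariate design) reduces exactly to the ordinary Cox fit, and
a cluster-robust no-frailty alternative is provided. Subgroup curves
exponentiate the Breslow baseline cumulative hazard with each pattern's
linear predictor relative to the covariate mean.

## Problem sizes and numerical conventions

Simulation-based checks in the test suite use reduced problem sizes
chosen to make their statistical bounds sharp but cheap: coverage of
the ordinal model's Wald CIs uses 200 replications of 150 subjects × 4
visits; Cox log-hazard recovery 100 replications of n=500; log-rank
type-I error 300–500 replications of n=100; calibration nulls n=400–600
with 5–8 outer CV iterations. The acceptance script runs the full
pipeline at 500 subjects with 6 outer CV iterations. Ties in the prox
map to zero; quadrature node counts are required odd so a node sits at
the mode; all randomness flows from one root seed through named
per-stage substreams (SHA-256 of `seed:stage`, reduced below 2^31).

## Known limitations

- Single random intercept only: no random slopes, no non-proportional
  odds, no time-varying covariates in the Cox model.
- The MCI class is derived, not directly modelled, in the multitask
  extension; its probability can require clipping.
- Imputation uncertainty is not propagated into model standard errors.
- The generator's absorption post-processing means generated data do
  not follow the fitted ordinal model exactly at later visits; fitted
  effects on such cohorts are systematically steeper than `beta*`,
  which is why recovery tests simulate from the exact model instead.
- Whether the onset time axis should read "since symptom onset" or
  "since diagnosis" is ambiguous in the motivating literature; both
  interpretations are supported via the `onset` scale (the generator
  does not distinguish symptom onset from diagnosis).
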