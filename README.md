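# binmr

Mendelian randomization (MR) estimators and bias diagnostics for the
all-binary setting: a binary genetic instrument Z, a binary exposure X and a
binary outcome Y.

When both traits are binary, genetic associations live on the log-odds
scale and the classic Wald ratio `β = γ₁/α₁` (instrument–outcome slope over
instrument–exposure slope) no longer targets the causal effect, because odds
ratios are noncollapsible. `binmr` implements the estimators used to study
this problem and the Monte-Carlo machinery to quantify how far each Wald
variant sits from the instrumental-variable estimators:

**Wald ratios** (all reported on the log-odds scale)

- *logistic*: `γ̂₁/α̂₁` from two logistic regressions on Z;
- *LPM*: the ratio of linear-probability-model (OLS) slopes, mapped to
  log-odds by the inverse prevalence transformation
  `β_logistic = β_linear / (pr·(1−pr))` with `pr` the outcome prevalence;
- *transformation*: logistic slopes mapped to the linear scale with
  `β_linear = β_logistic·pr·(1−pr)` (each slope with its own trait's
  prevalence), ratio taken on the linear scale, then mapped back.

**Instrumental-variable estimators**

- *SEM*: logistic regression of Y on X (plus covariates) — with binary
  responses a simultaneous two-equation system has no cross-equation error
  term, so joint and sequential maximum likelihood coincide;
- *TSPS* (two-stage predictor substitution): logistic Y on the first-stage
  fitted probability `P̂ₓ`;
- *TSRI* (two-stage residual inclusion): logistic Y on X and the first-stage
  residual `ε̂ₓ = X − P̂ₓ`.

The *bias* of a Wald variant is the per-replicate difference
`IV estimate − Wald estimate`, summarized by median and quartiles over
thousands of simulated cohorts drawn from a confounded bivariate-Bernoulli
model:

    Z ~ Bernoulli(pZ),  U ~ N(0,1)
    X ~ Bernoulli(expit(α₀ + α₁Z + cx·U))
    Y ~ Bernoulli(expit(β₀ + β₁X + cy·U))

An applied workflow runs the same estimators, adjusted for observed binary
confounders, on a subject-level cohort table (CSV, optionally a PLINK
`--recode A` `.raw` genotype export), with a chi-square / Fisher's-exact
SNP–exposure association screen.

## Worked example

```python
import numpy as np
from binmr import BinaryIVMR, SimulationConfig, draw_dataset

cfg = SimulationConfig(alpha1=0.7, beta1=1.0, cx=0.01, cy=0.01,
                       n=100_000, seed=7, n_reps=1)
ds = draw_dataset(cfg, 0)
res = BinaryIVMR(outcome=ds.Y, exposure=ds.X, instrument=ds.Z).fit()
print(res.summary())
```

```
Binary-instrument Mendelian randomization
=========================================================
n = 100000    P(X=1) = 0.533    P(Y=1) = 0.623
---------------------------------------------------------
method                    estimate   valid
---------------------------------------------------------
wald_logistic               0.2524    True
wald_lpm                    1.0351    True
wald_transformation         1.0142    True
sem                         1.0278    True
tsps                        1.0499    True
tsri                        1.0549    True
---------------------------------------------------------
estimates on the log-odds scale; IV minus Wald differences
available via .bias_matrix()
```

The true causal effect is `β₁ = 1` on the log-odds scale. SEM, TSPS and
TSRI sit near 1, and so do the LPM and transformation Wald ratios, while
the logistic Wald ratio (0.25) is attenuated by noncollapsibility — the
pattern the bias study quantifies. `res.bias_matrix()` returns the 3×3
IV-minus-Wald table for this dataset.

The replicated study is one call (or `binmr simulate` from a shell):

```python
from binmr import build_core_grid, run_study
table = run_study(build_core_grid(seed=0), reps_override=2000)
```

which yields one `median, q1, q3, n_valid` row per scenario (A–D), per
instrument strength (0.01 … 0.7) and per estimator pair. By default the
simulated confounder U enters every regression stage as an observed
covariate, matching the applied analysis; pass `adjust_confounder=False`
to withhold it and study pure unobserved confounding.

## Layout

- `binmr.simulate` — data-generating process, scenario and sensitivity grids
- `binmr.estimators` — regression kernels and the six estimators
- `binmr.model` — `BinaryIVMR` / `BinaryIVMRResults` interface
- `binmr.bias_study` — replicated study, quantile summaries, tidy exports
- `binmr.applied` — cohort-table workflow, SNP screen, fixture generator
- `binmr.cli` — `binmr simulate`, `binmr analyze`

See `docs/methods.md` for the statistical details and design choices.
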