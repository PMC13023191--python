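# Methods

## The estimation problem

With a single binary instrument Z, binary exposure X and binary outcome Y,
genetic associations are naturally expressed as log-odds ratios. The Wald
ratio — (instrument–outcome association)/(instrument–exposure association) —
is the workhorse of two-sample Mendelian randomization, but on the log-odds
scale it does not recover the conditional causal effect even when the
instrument is valid, because odds ratios are noncollapsible: the marginal
log-odds effect of Z on Y is not the conditional effect of X on Y scaled by
the Z→X effect. `binmr` implements three Wald variants and three
instrumental-variable estimators so the gap between them can be measured by
simulation and inspected on real cohorts.

## Estimators

All six estimators consume per-subject `(Z, X, Y)` plus optional named
binary/real covariates, which enter **every** regression stage.

Wald ratios:

1. **Logistic.** Fit `Logit P(X=1) = α₀ + α₁Z` and `Logit P(Y=1) = γ₀ + γ₁Z`;
   report `γ̂₁/α̂₁`.
2. **LPM.** Fit the same two regressions by ordinary least squares on the
   probability scale (the linear probability model); the slope ratio is a
   probability-scale effect, mapped to log-odds by the inverse prevalence
   transformation `β_logistic = β_linear/(p̄_Y(1−p̄_Y))`, where `p̄_Y` is the
   sample outcome prevalence. Plain OLS is used, not the two-step weighted
   variant; heteroscedasticity affects efficiency, not the point estimate.
3. **Transformation.** Fit the two logistic regressions, map each slope to
   the linear scale with `β_linear = β_logistic·p̄·(1−p̄)` using its own
   trait's sample prevalence, take the ratio, and map back with the outcome
   prevalence. Algebraically the result equals the logistic Wald ratio
   divided by `p̄_X(1−p̄_X)`; at equal prevalences the two prevalence factors
   cancel inside the ratio (the linear-scale ratio equals the logistic Wald
   ratio) while the final back-transform keeps the exposure factor. The
   prevalences actually used are recorded on the result for audit.

Instrumental-variable estimators:

4. **SEM.** The two-equation system `Logit P(X) = α₀+α₁Z`,
   `Logit P(Y) = β₀+β_sem·X`. With Bernoulli responses there is no
   cross-equation error term to correlate, so simultaneous maximum
   likelihood factorizes into the two logistic fits; the outcome equation
   (Y on X plus covariates, the instrument never entering) carries the
   estimate.
5. **TSPS.** Stage 1: logistic X on Z; stage 2: logistic Y on the fitted
   probability `P̂ₓ`. The estimate is the coefficient on `P̂ₓ`.
6. **TSRI.** Stage 1 as TSPS; stage 2: logistic Y on X and the residual
   `ε̂ₓ = X − P̂ₓ`. The estimate is the coefficient on X, with the residual
   coefficient reported alongside.

Bias of a Wald variant, per replicate, is `IV estimate − Wald estimate`
(so a positive entry means the IV estimator sits above the Wald ratio).

## Fitting kernels and numerical policy

All logistic stages share one Newton/IRLS kernel with step halving:
convergence when the relative log-likelihood change drops below 1e-8,
at most 100 iterations. Standard errors come from the inverse observed
information. The kernel flags rather than raises on degenerate replicates:

- **Separation** — non-convergence, or any non-intercept coefficient
  exceeding 15 on the column-standardized scale — yields `converged=False`
  and the downstream estimate is marked invalid (never a silent zero).
- **Rank deficiency** — condition number of the weighted normal matrix
  above 1e10, or a singular solve — likewise invalidates the estimate.
  This matters for TSPS/TSRI when the fitted first stage is almost flat
  (`α̂₁ ≈ 0`), making `P̂ₓ` nearly constant and X nearly collinear with its
  residual.
- **Ratio floor** — Wald ratios with `|denominator| < 1e-8` are invalid.
- A constant response or a user-supplied constant covariate is an input
  error and raises.

Valid estimates are never winsorized or capped: weak-instrument cells
legitimately produce enormous ratios, and the quartile summaries are
computed over valid entries only, with the count of failures reported
(`n_valid + failures = n_reps` per pair and cell).

Quantiles use linear interpolation between order statistics (the
numpy/R type-7 default): for `{1,2,3,4}` that gives Q1 = 1.75,
median = 2.5, Q3 = 3.25.

## Data-generating process

Each replicate draws, i.i.d. per subject:

    Z ~ Bernoulli(pZ)                       instrument, default pZ = 0.2
    U ~ Normal(0, 1)                        confounder
    X ~ Bernoulli(expit(α₀ + α₁Z + cx·U))   exposure
    Y ~ Bernoulli(expit(β₀ + β₁X + cy·U))   outcome

Defaults: n = 1000 subjects, α₀ = β₀ = 0, 8000 replicates per cell.
The core grid crosses scenarios A (β₁=0, cx=cy=0.01), B (β₁=0, cx=cy=1.5),
C (β₁=1, cx=cy=0.01) and D (β₁=1, cx=cy=1.5) with instrument strengths
α₁ ∈ {0.01, 0.05, 0.1, 0.5, 0.7}. Four sensitivity grids vary sample size
{50, 200, 500, 1000, 1500}, instrument prevalence {0.1, 0.2, 0.5, 0.8},
trait prevalence via (α₀, β₀) ∈ {(0,0), (1,1), (3,3), (−2,−2)}, and
confounder effect {0.01, 0.1, 0.5, 1, 1.5, 2}; the grid builders enforce
cx = cy because no study condition varies them separately. Per-configuration
trait prevalences are regenerated by `prevalence_summary` rather than
hard-coded.

**Confounder visibility.** By default the bias study supplies U to every
regression stage of every estimator as an observed covariate — the design
treats the simulated confounder exactly like the measured confounders of
the applied analysis, and the strong-confounding scenario summaries are
defined under that convention (without it, the SEM-based medians shift
upward by roughly the confounding bias of Y|X, about +1 at cx=cy=1.5).
`adjust_confounder=False` withholds U and gives the textbook
unobserved-confounding setting; the dataset object always carries U for
diagnostics either way.

**Reproducibility.** Every replicate's random stream is seeded by the pair
`(cell seed, replicate index)` via a `SeedSequence`, so any replicate can be
regenerated in isolation and results are bitwise identical regardless of
worker count or scheduling. Grid builders derive per-cell seeds from one
master seed.

## Replicate scale and Monte-Carlo tolerances

The study scale is 8000 replicates per cell; the test suite runs 2000 per
cell so the full end-to-end checks complete in a few minutes on one CPU.
At 2000 replicates the standard error of a median is roughly
`1.25·IQR/(1.35·√2000)`; for pairs whose bias IQR is ~2 that is ~0.04, and
test tolerances are set at ±0.1 (narrow-IQR cells) and ±0.3 (wide-IQR
cells) accordingly. Pairs whose bias distribution has IQR ~8 (the SEM
versus LPM/transformation pairs at α₁ = 0.01) have median standard error
~0.17 at 2000 replicates: their medians cannot be pinned down to better
than a few tenths at this scale, and the suite's check that medians stay
within 0.15 of each other across instrument-prevalence settings is
expected to fail for exactly those pairs — it is retained as a known-red
check rather than loosened, since the qualitative claim it encodes is not
statistically attainable at any feasible replicate count.

## Applied workflow

`read_subject_table` validates a flat CSV (0/1 coding enforced, offending
rows reported; rows missing exposure or outcome retained but flagged).
`read_plink_raw` maps additive dosages {0,1,2,NA} from a PLINK
`--recode A` export to a binary instrument; the default **carrier** coding
(dosage ≥ 1 → 1) is a modelling choice, with dominant/recessive/major
alternatives, because no canonical dichotomization exists. Genotype QC
(missingness, HWE, MAF, relatedness, LD pruning) is a documented
prerequisite, performed upstream with PLINK.

`snp_screen` tests each SNP against the exposure on the complete-case 2×2
table: Pearson chi-square (uncorrected) when every expected count is at
least 5, otherwise two-sided Fisher's exact. `select_snps` ranks by p-value
deterministically, with an optional seeded draw from the top-k.
`analyze_snp` runs all six estimators with the confounders in both stages
of every method, on complete cases per SNP (so per-SNP n varies with
missingness), and reports the estimates, the 3×3 bias matrix and the
SEM coefficient panels with 95% CIs.

## The fixture generator

`make_fixture` emulates the structure of a prospective dog-cohort cancer
study: ~2340 subjects, a binary high-activity exposure at prevalence 0.18,
a binary cancer outcome at prevalence 0.091, five binary SNP instruments
(carrier frequency 0.2, log-odds effects ≈ 0.64–0.69 on the exposure) and
four binary confounders (sex and three environmental exposures) entering
both equations; per-SNP genotype missingness 0.3% so complete-case counts
differ across SNPs. Confounder prevalences (0.5, 0.5, 0.4, 0.3) are
plausible cohort values chosen once. Intercepts are not free parameters:
they are calibrated by Brent root finding on the empirical mean of
`expit(b + η)` so realized prevalences hit the targets; unattainable
targets raise a calibration error.

What the fixture does **not** emulate: linkage disequilibrium between the
SNPs (they are independent here, so per-SNP marginal instrument strengths
attenuate below the generating effects when several SNPs carry signal),
genotyping error, informative missingness, and any real exposure–outcome
biology. Passing fixture-based tests therefore demonstrates correctness of
the estimation pipeline, not epidemiological claims; cohort-scale results
require the external study data, which ship with the study, not with this
package.

## Known limitations

- No standard errors or confidence intervals for the Wald ratios (the
  stage-level fits expose their own standard errors); no weak-instrument
  F-statistics; no multi-instrument (IVW) combination; single valid IV
  assumed, no pleiotropy modelling.
- The LPM uses plain OLS; predicted probabilities outside [0,1] are
  inherent to that model and left untouched.
- TSPS and TSRI estimates are reported independently even when numerically
  close; no agreement is enforced.
- Percentage bias is deliberately not computed: the estimand scale differs
  across frameworks, making relative bias misleading.
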