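# Methods

## The synthetic study generator

`simulate_study` emulates a retrospective two-group survival cohort
profiled on a log2-intensity expression platform.

**Expression.** Each gene's background is Gaussian with mean drawn
uniformly on [6, 12] and SD on [0.3, 1.0] — typical log2 bead-array
ranges that keep t-statistics on a realistic scale. The first
`n_signal_genes` probes are shifted between the good and poor groups by
`effect_size` log2 units, alternating direction so the panel contains
both up- and down-regulated genes.

**Survival.** The linear predictor is η = βᵀZ, where Z is the Z-scored
signal-gene expression and the true coefficients β have magnitude
`effect_size/15` (0.1 at the default effect of 1.5) with signs matching
each gene's shift; event times are exponential with rate
`baseline_hazard · exp(η)`. The default baseline hazard ln2/60 per month
gives a median survival of 60 months for an average patient. Because the
emulated cohort is *retrospectively selected* by five-year outcome —
equal numbers of patients who died within 60 months and patients who
survived past it — event times are drawn from the proportional-hazards
exponential conditional on the planted class: truncated below 60 months
for the poor group and, using memorylessness, shifted past 60 for the
good group. Without this conditioning, exponential noise relabels roughly
a fifth of samples under the five-year class rule and the class contrast
no longer equals the planted effect size; the conditional draw reproduces
the case–control structure of a survival-selected cohort while keeping
the hazard model intact.

**Censoring.** An independent exponential censoring time is calibrated by
bisection so the expected censored fraction matches `censoring_rate`,
with an administrative cutoff at `follow_up_horizon` (120 months). When
long survivors make administrative censoring alone exceed the target —
unavoidable in a cohort built to split at 60 months and followed to 120 —
the random-censoring rate goes to zero and the realized censored fraction
sits at that floor; the calibration is exact whenever the floor does not
bind.

**Contamination.** A fraction `contamination_rate` of observations is
replaced by gross outliers at ±`contamination_shift` SDs from the
gene/group mean (point contamination in the Tukey–Huber sense), injected
after the survival draw as a pure measurement artifact. The planted mask
is kept as ground truth.

**Class labels.** The clinical table derives `class` from follow-up: good
if time ≥ 60 months, poor if death before 60, NA for samples censored
early (too little follow-up to classify). NA samples are excluded from
class-based analyses but retained for Cox fitting.

What the generator does **not** emulate: probe-level assay chemistry,
batch or spatial artifacts, correlated gene modules, non-proportional
hazards, and informative censoring. Passing recovery tests on this model
therefore demonstrates that the pipeline's machinery works under its own
assumptions, not that real cohorts satisfy those assumptions.

## Robust outlier diagnosis

The per-gene, per-group estimator iterates

    μ_{t+1}  = Σ ψ_β(x|θ_t) x / Σ ψ_β(x|θ_t)
    σ²_{t+1} = (β+1) · Σ ψ_β(x|θ_t) (x−μ_t)² / Σ ψ_β(x|θ_t)

with ψ_β(x|θ) = exp(−(β/2)·((x−μ)/σ)²), starting from the median and
1.4826·MAD (falling back to the classical SD when the MAD is zero).
The (β+1) factor makes σ̂² consistent at the Gaussian; as β → 0 the fixed
point is exactly the sample mean and the MLE variance. Convergence is
declared when max(|Δμ|, |Δσ²|) < tol·σ̂² (tol = 1e-8, cap 100 iterations).
All-identical values are a degenerate-variance error.

**Flagging and the refinement loop.** An observation is contaminated when
its converged weight falls below 0.2, i.e. beyond |z| = √(2·ln5/β) ≈ 4.01
SDs at β = 0.2. A single converged fit, however, loses power against
*clustered* contamination: with five or more gross errors among 39
observations the fixed-point σ̂ inflates enough (≈ 60%) that the entire
cluster's weights rise back above 0.2 and nothing is flagged. The
diagnosis therefore iterates: candidate gross errors are first screened
with ψ evaluated at the median/MAD starting point (which a minority
cluster cannot corrupt), the estimators are refit on the retained
observations, and flagging repeats until the flag set stabilizes (at most
20 passes, always retaining at least the three highest-weight
observations per gene). The final flags are still defined by ψ < 0.2 at
the final estimates. This restores high recall at double-digit per-group
contamination while leaving the false-flag rate at the ~4-SD Gaussian
tail level.

**Replacement.** Flagged values are replaced by a uniform draw inside the
group's 90% robust confidence interval μ̂ ± 1.644·σ̂/√n (the printed
1.644 multiplier is used verbatim rather than the four-digit normal
quantile). The draw is seeded and happens once, after the flag set is
fixed, so the mask is independent of the replacement seed; a
deterministic mode replacing with μ̂ is available (`replacement="mean"`).
The default β = 0.2 places the flag boundary at the conventional ~4-SD
gross-error threshold; β is a config field and is echoed in all outputs.

## Differential-expression signature

Splits are stratified by survival class so both halves keep the cohort's
class balance (equal within one sample; odd class counts donate their
leftover alternately to train and test). Per half and per round:

- **Welch t** with exact t-distribution p-values.
- **SAM**: d = (x̄₁−x̄₂)/(s+s₀) with the pooled gene-wise scatter
  s = √{(1/n₁+1/n₂)(ss₁+ss₂)/(n₁+n₂−2)}; s₀ defaults to the median of
  the s_i (a percentile-search variant is available). p-values come from
  class-label permutations pooled across genes (500 permutations by
  default) with the +1 correction.
- **Moderated t**: pooled variances are shrunk toward a prior estimated
  by method of moments on log variances (prior degrees of freedom from a
  Newton inversion of the trigamma equation); the statistic uses the
  posterior variance and d₀ + d degrees of freedom. When the observed
  log-variance spread is no larger than its sampling noise the prior is
  taken as infinite and all genes share one variance.

All p-values are Benjamini–Hochberg adjusted; top-k selection sorts by
adjusted p with ties broken by larger |statistic| then probe id, so the
selection is deterministic. The per-round set is the six-way intersection
(three methods × two halves); the signature is every gene present in at
least `freq_threshold` (default 0.95) of rounds. The full frequency table
is recorded so any other combination rule can be audited after the fact.
The half-splits are drawn without replacement by default; a bootstrap
mode exists but is off.

With 20,793 probes the study-scale top-k is 1500 (≈ 7% of the genome);
desk-scale runs on 2000 genes use the proportional k = 150.

## Penalized Cox model

The partial likelihood uses Breslow's treatment of tied event times
(risk sets are suffix sums over the time-sorted cohort, computed with a
log-sum-exp shift). Fitting maximizes l(β) − λ₁Σ|β| − λ₂Σβ² by cyclic
coordinate-wise Newton steps soft-thresholded at λ₁: for coordinate j
with gradient g and curvature h, the update is
S(h·β_j + g, λ₁)/(h + 2λ₂). Steps are clipped to ±2 and a pass that
decreases the penalized objective is re-run at half step, so the
objective is nondecreasing; convergence requires the largest coefficient
change in a pass below 1e-7. λ₁ = λ₂ = 0 reproduces the unpenalized MLE
(cross-checked against a full-Newton solver and independent optimizers);
λ₁ above max_j |∂l/∂β_j(0)| gives exactly β = 0. A coefficient magnitude
above 15 on standardized covariates (hazard ratio > 3×10⁶) is treated as
monotone-likelihood divergence and raises an error advising a positive
penalty.

**Penalty tuning.** CVL(λ₁, λ₂) = Σ_k [l_full(β̂₋ₖ) − l₋ₖ(β̂₋ₖ)], the
leave-one-fold-out cross-validated partial log-likelihood. Folds (10 by
default) are assigned at random, re-drawn if any training complement has
no events. A 5×5 log-spaced grid spanning three decades below the
full-shrinkage λ₁ is scanned first (strongest penalties first, each
fold's previous solution warm-starting the next fit — a pure speed
optimization, since every fit runs to the same tolerance); the best cell
then seeds Nelder–Mead refinements in log-penalty space from `starts`
random restarts. The desk default is 10 restarts (configurable to 50);
restarts affect only the optimizer's robustness on the flat CVL surface,
not the objective. The model is refit on all data at the winning pair.
Everything is deterministic given the seed.

**Stratification and tests.** Risk scores are βᵀX on per-gene Z-scored
expression (n−1 denominator; zero-variance genes map to zero with a
warning so flat probes in external cohorts cannot abort scoring). The
cutoff is the mid-rank median of training scores, frozen for any test or
external cohort; a score equal to the cutoff is high-risk. Group
separation uses the Cox likelihood-ratio test on the group indicator
(χ², 1 df) with the Wald hazard ratio and 95% CI; when one group has no
events the HR is unbounded and is reported from a capped fit with a
one-sided interval and a warning. Kaplan–Meier curves (with Greenwood
bands) come from lifelines. Per-covariate univariate/multivariate hazard
tables use the full-Newton fit with Wald CIs; singular information
matrices raise a collinearity error naming the covariates. External
application restricts to the signature genes present (warning lists
absences), Z-scores within the cohort, and reuses the training
coefficients and cutoff — coefficients are never refit on validation
data.

## Evaluation statistics

Signed fold changes use the negative-reciprocal convention on log2 data:
logFC = mean(poor) − mean(good), reported as 2^logFC when up-regulated
and −2^(−logFC) when down-regulated, so |FC| ≥ 1 always and a halving
reads −2.0. qPCR concordance follows 2^-ΔΔCt with ΔCt = Ct(target) −
Ct(reference) and the good-survival group as calibrator.
Sensitivity/specificity take poor survival as the positive class.
Fisher's exact test is two-sided by the probability-mass rule (2×2
only); the chi-square test is Pearson's without continuity correction.

## Problem sizes and defaults

Desk-scale analyses run at 2000 genes × 78 samples (39/39), 19 signal
genes at effect 1.5, 7.7% contamination at 6 SD, 100 split rounds,
top-k 150, 10 CV folds and 10 tuning restarts; the acceptance script uses
these sizes throughout and completes in a few minutes on one CPU. The
study-scale geometry (20,793 probes, top-k 1500, 50 restarts) is reached
purely through configuration.

## Known limitations

- Cohort-specific published quantities (the exact gene identities of a
  real signature, a real cohort's risk-score cutoff or hazard ratios)
  cannot be reproduced without the original data; the tests instead
  verify recovery of planted truth under the generator's assumptions.
- The β-divergence fixed point without the refinement loop loses
  clustered outliers (documented above); the refinement is this package's
  remedy, not part of the core estimator.
- CVL surfaces at n ≈ 78 are flat near the optimum, so the selected
  (λ₁, λ₂) pair is seed-stable but not scientifically unique; coefficient
  signs and the risk ranking are far more stable than the penalty values.
- The LRT under perfect group separation relies on a capped fit; its
  statistic is then a function of the rank structure only.
- Quantile normalization assumes comparable global distributions across
  samples; it is not applied to data already on the log scale unless
  requested.
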