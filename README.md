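# prognosig

Prognostic gene-signature discovery and survival risk stratification for
expression cohorts with survival annotation — built for the setting where a
retrospective tumour cohort (e.g. FFPE colorectal-cancer samples profiled on
a bead array) is split into good and poor five-year-survival groups and the
goal is a small gene panel whose expression predicts overall survival.

The pipeline chains four statistical stages:

1. **Robust outlier cleaning.** Expression artifacts are diagnosed per gene
   and survival group with the minimum β-divergence estimator. Each
   observation receives the weight ψ_β(x | μ, σ) = exp(−(β/2)·((x−μ)/σ)²);
   the robust mean and variance are the fixed point of the ψ-weighted
   updates μ ← Σψx/Σψ and σ² ← (β+1)·Σψ(x−μ)²/Σψ. Observations with
   ψ < 0.2 (beyond ≈ 4 SD at the default β = 0.2) are flagged and replaced
   by a draw from the 90% robust confidence interval μ̂ ± 1.644·σ̂/√n of
   their group mean.
2. **Permutation-intersection signature selection.** The class-labelled
   samples are split 100 times into stratified train/test halves. In each
   half three differential-expression statistics are computed per gene —
   Welch t, a SAM statistic d = (x̄₁−x̄₂)/(s+s₀) with permutation p-values,
   and an empirical-Bayes moderated t — and each method's top-k genes (by
   Benjamini–Hochberg adjusted p) are intersected across methods and then
   across the two halves. Genes surviving in ≥ 95% of rounds form the
   signature.
3. **Elastic-net Cox risk model.** Coefficients maximize the penalized
   partial log-likelihood l(β) − λ₁Σ|β_i| − λ₂Σβ_i² (Breslow ties) by
   cyclic coordinate-wise Newton updates with soft-thresholding; (λ₁, λ₂)
   are tuned by maximizing the cross-validated partial log-likelihood
   (CVL) with 10-fold cross-validation and multistart refinement. Each
   patient's risk score is βᵀX over Z-scored signature expression.
4. **Stratification and validation.** Patients are split at the training
   median risk score (score ≥ cutoff → high risk); separation is tested by
   the Cox likelihood-ratio test with Kaplan–Meier curves per group, and
   the panel is transported to external cohorts by per-cohort Z-scoring
   with the frozen training coefficients and cutoff. Descriptive
   statistics (signed fold changes, qPCR 2^-ΔΔCt concordance,
   sensitivity/specificity, Fisher/chi-square contingency tests) round out
   the reporting.

A synthetic-study generator (`prognosig.synthetic`) produces cohorts with
the same structure — grouped log2-intensity expression, planted
differentially expressed genes, gross-outlier contamination, and
right-censored survival driven by a proportional-hazards model — together
with full ground truth, so every stage can be scored on recovery.

## Worked example

```python
from prognosig import (PipelineConfig, SimulationConfig, run_pipeline,
                       simulate_study)

study = simulate_study(SimulationConfig(n_genes=1000, n_signal_genes=10,
                                        seed=7))
config = PipelineConfig(output_dir="demo_out", log_transform="none",
                        n_rounds=25, top_k=75, seed=7)
result = run_pipeline(config, expression=study.expression,
                      clinical=study.clinical)

print("flagged as contaminated:",
      f"{100 * result.metrics['fraction_contaminated']:.2f}%")
print("signature genes:", result.signature.genes)
print("planted genes:  ", study.signal_genes)
print(f"median risk-score cutoff: {result.model.cutoff:.3f}")
print(f"high vs low risk LRT: chi2={result.stratification.lrt.statistic:.1f}, "
      f"p={result.stratification.lrt.p:.3g}")
```

prints

```
flagged as contaminated: 7.26%
signature genes: ['G00000', 'G00001', 'G00002', 'G00003', 'G00004', 'G00005', 'G00006', 'G00007', 'G00008', 'G00009']
planted genes:   ['G00000', 'G00001', 'G00002', 'G00003', 'G00004', 'G00005', 'G00006', 'G00007', 'G00008', 'G00009']
median risk-score cutoff: -0.077
high vs low risk LRT: chi2=103.3, p=2.86e-24
```

The cleaning stage flags 7.26% of observations (7.7% were planted), the
signature recovers exactly the ten planted genes, and the median-cutoff
risk groups separate overwhelmingly (χ² = 103.3 on 1 df). The same
pipeline is available from the shell:

```sh
prognosig simulate --out study/ --seed 7 --genes 1000 --signal-genes 10
prognosig run-all --expression study/expression.tsv \
                  --clinical study/clinical.tsv --out results/ --seed 7
```

Outputs are plain TSV/JSON: `signature.tsv` (gene, selection frequency),
`model.json` (coefficients, penalties, cutoff, CVL), `stratification.tsv`,
`km_curves.tsv`, `outliers.tsv` and `metrics.json`.

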