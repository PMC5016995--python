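"""Descriptive and validation statistics around the signature.

Covers signed fold changes on the log2 scale (negative-reciprocal
convention for down-regulation), qPCR 2^-ΔΔCt concordance, classifier
sensitivity/specificity, clinical contingency tests (Fisher exact /
Pearson chi-square), and application of a trained risk model to an
external cohort with per-cohort Z-scoring at the frozen training cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (ClinicalTable, DataError, ExpressionMatrix,
                         ParameterError)
from .preprocess import z_transform
from .riskmodel import (CoxRiskModel, RiskStratification,
                        evaluate_stratification, risk_scores,
                        stratify_by_median)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion table; positive class = poor survival."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ParameterError("counts must be nonnegative")
        if self.tp + self.fn + self.tn + self.fp == 0:
            raise ParameterError("confusion table is empty")


def fold_change(m: ExpressionMatrix, classes, gene: str) -> tuple[float, str]:
    """Signed fold change of a gene in the poor vs good group.

    On log2 data, logFC = mean(poor) − mean(good); the signed fold change
    is 2^logFC when up-regulated and −2^(−logFC) when down-regulated, so
    a halving reads as −2.0 rather than 0.5. Returns (fold change,
    'Up-regulated' | 'Down-regulated').
    """
    if gene not in m.values.index:
        raise KeyError(f"gene {gene!r} not in matrix")
    classes = pd.Series(classes)
    if set(m.sample_ids) <= set(classes.index):
        classes = classes.loc[m.sample_ids]
    row = m.values.loc[gene].to_numpy(dtype=float)
    poor = row[(classes == "poor").to_numpy()]
    good = row[(classes == "good").to_numpy()]
    if len(poor) == 0 or len(good) == 0:
        raise ParameterError("both classes must be nonempty")
    logfc = float(poor.mean() - good.mean())
    if logfc >= 0:
        return float(2.0**logfc), "Up-regulated"
    return float(-(2.0 ** (-logfc))), "Down-regulated"


def delta_delta_ct(records: pd.DataFrame, calibrator_group: str = "good") -> pd.Series:
    """Per-gene relative expression by the 2^-ΔΔCt method.

    ``records`` columns: sample_id, gene_id, ct_target, ct_reference,
    group. ΔCt = Ct(target) − Ct(reference) per sample; ΔΔCt is the test
    group's mean ΔCt minus the calibrator group's; the result is 2^-ΔΔCt
    per gene.
    """
    required = {"sample_id", "gene_id", "ct_target", "ct_reference", "group"}
    missing = required - set(records.columns)
    if missing:
        raise DataError(f"qPCR records missing columns {sorted(missing)}")
    if records["ct_reference"].isna().any() or records["ct_target"].isna().any():
        bad = records.loc[records["ct_reference"].isna()
                          | records["ct_target"].isna(), "sample_id"].tolist()
        raise DataError(f"missing Ct values for samples {bad[:5]}")
    groups = set(records["group"])
    if calibrator_group not in groups:
        raise ParameterError(f"calibrator group {calibrator_group!r} absent")
    dct = records.assign(dct=records["ct_target"] - records["ct_reference"])
    out = {}
    for gene, sub in dct.groupby("gene_id"):
        cal = sub.loc[sub["group"] == calibrator_group, "dct"].mean()
        test = sub.loc[sub["group"] != calibrator_group, "dct"].mean()
        out[gene] = float(2.0 ** (-(test - cal)))
    return pd.Series(out, name="relative_expression")


def classification_metrics(c: ConfusionCounts) -> tuple[float, float]:
    """(sensitivity, specificity) in percent."""
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ParameterError("empty margin: sensitivity/specificity undefined")
    sens = 100.0 * c.tp / (c.tp + c.fn)
    spec = 100.0 * c.tn / (c.tn + c.fp)
    return float(sens), float(spec)


def contingency_test(table, method: str = "fisher"):
    """p-value (and odds ratio for 2×2 Fisher) of a contingency table.

    Fisher: two-sided exact test summing hypergeometric probabilities no
    larger than the observed table's (2×2 only). chi2: Pearson statistic
    without continuity correction, df = (r−1)(c−1).
    """
    t = np.asarray(table)
    if t.ndim != 2 or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.floor(t)):
            raise ParameterError("counts must be nonnegative integers")
        t = t.astype(int)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DataError("degenerate table: zero row or column margin")
    if method == "fisher":
        if t.shape != (2, 2):
            raise ParameterError("Fisher's exact test requires a 2×2 table")
        odds, p = stats.fisher_exact(t, alternative="two-sided")
        return float(p), float(odds)
    if method == "chi2":
        chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
        return float(p), float(chi2)
    raise ParameterError(f"unknown method {method!r}")


def apply_signature_external(
    model: CoxRiskModel,
    expression: ExpressionMatrix,
    clinical: ClinicalTable,
) -> RiskStratification:
    """Score an external cohort with the trained model.

    Restricts to the signature genes present in the cohort (warning when
    some are absent), Z-scores them within the cohort, applies the
    training coefficients and the frozen training cutoff, and returns the
    stratification with per-group KM curves and the group LRT.
    """
    genes = list(model.coefficients.index)
    present = [g for g in genes if g in expression.values.index]
    absent = [g for g in genes if g not in present]
    if not present:
        raise DataError("no signature gene present in the cohort")
    if absent:
        warnings.warn(f"signature genes absent from cohort: {absent}")
    if model.cutoff is None:
        raise ParameterError("model has no training cutoff; stratify training first")

    sub = expression.subset_probes(present)
    z = z_transform(sub.with_state("normalized") if sub.state == "zscored" else sub)
    partial = CoxRiskModel(
        coefficients=model.coefficients.loc[present],
        lambda1=model.lambda1, lambda2=model.lambda2,
        loglik=model.loglik, cvl=model.cvl, cutoff=model.cutoff,
    )
    scores = risk_scores(partial, z)
    clin = clinical.aligned_to(list(scores.index))
    strat = stratify_by_median(scores, cutoff=model.cutoff)
    strat.missing_genes = absent
    return evaluate_stratification(strat, clin.time, clin.event)
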