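"""Readers, writers, configuration and the end-to-end pipeline driver.

File dialects
-------------
Expression TSV: first column ``probe_id``, remaining columns sample ids,
tab-delimited, '.' decimal; the processing state travels in a sidecar
``<file>.state.json``. Clinical TSV columns: sample_id, time_months,
event (0/1), class (good|poor|NA), stage (B|C|NA), age, gender (M|F).
"""

from __future__ import annotations

import json
import logging
import time as _time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import ClinicalTable, DataError, ExpressionMatrix
from .evaluation import ConfusionCounts, classification_metrics, fold_change
from .preprocess import log2_and_baseline, median_baseline, quantile_normalize, z_transform
from .riskmodel import (CoxRiskModel, PenaltyConfig, SurvivalData,
                        evaluate_stratification, risk_scores,
                        stratify_by_median, tune_penalties_cvl)
from .robust import OutlierConfig, detect_and_replace
from .signature import GeneSignature, SplitScheme, permutation_signature

log = logging.getLogger("prognosig")


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return (int(master) ^ zlib.crc32(stage.encode())) % (2**31)


# ------------------------------------------------------------------ readers

def read_expression(path: str | Path, state: str | None = None) -> ExpressionMatrix:
    """Read an expression TSV; ids kept verbatim, duplicates rejected."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"duplicate probe ids in {path.name}: {dups[:5]}")
    numeric = df.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r = int(np.argmax(bad.any(axis=1).to_numpy()))
        raise DataError(
            f"non-numeric cell in {path.name} at line {r + 2} "
            f"(probe {df.index[r]!r})")
    if numeric.isna().to_numpy().any():
        r = int(np.argmax(numeric.isna().any(axis=1).to_numpy()))
        raise DataError(f"missing value in {path.name} at line {r + 2}")
    if state is None:
        sidecar = path.with_name(path.name + ".state.json")
        state = (json.loads(sidecar.read_text())["state"]
                 if sidecar.exists() else "raw")
    return ExpressionMatrix(numeric.astype(float), state=state)


def write_expression(m: ExpressionMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = m.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
    path.with_name(path.name + ".state.json").write_text(
        json.dumps({"state": m.state}))
    return path


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV; event coerced to {0,1}, NA categories allowed."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str},
                     na_values=["NA"], keep_default_na=True)
    if "event" in df.columns:
        df["event"] = pd.to_numeric(df["event"], errors="coerce")
    return ClinicalTable(df)


def write_signature(sig: GeneSignature, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"gene_id": list(sig.frequency.index),
                  "frequency": sig.frequency.to_numpy()}).to_csv(
        path, sep="\t", index=False, float_format="%.6g")
    return path


def write_model(model: CoxRiskModel, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({
        "genes": list(model.coefficients.index),
        "coefficients": [round(float(v), 12) for v in model.coefficients],
        "lambda1": model.lambda1,
        "lambda2": model.lambda2,
        "cutoff": model.cutoff,
        "cvl": model.cvl,
    }, indent=1, sort_keys=True))
    return path


def read_model(path: str | Path) -> CoxRiskModel:
    d = json.loads(Path(path).read_text())
    return CoxRiskModel(
        coefficients=pd.Series(d["coefficients"], index=d["genes"], name="beta"),
        lambda1=d["lambda1"], lambda2=d["lambda2"],
        loglik=float("nan"), cvl=d.get("cvl"), cutoff=d.get("cutoff"),
    )


# ------------------------------------------------------------- configuration

@dataclass
class PipelineConfig:
    """Everything needed to rerun the analysis end to end.

    Stage seeds derive deterministically from the master seed, so a rerun
    with an identical config reproduces identical outputs.
    """

    expression_path: str | None = None
    clinical_path: str | None = None
    output_dir: str = "prognosig_out"
    # preprocessing toggles
    quantile: bool = False
    log_transform: str = "median"  # 'log2' | 'median' | 'none'
    # stage parameters
    outlier: dict = field(default_factory=dict)
    n_rounds: int = 100
    top_k: int = 1500
    freq_threshold: float = 0.95
    sam_permutations: int = 500
    penalty: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class PipelineResult:
    """In-memory bundle of the pipeline outputs plus written paths."""

    signature: GeneSignature
    model: CoxRiskModel
    stratification: object
    outlier_report: object
    metrics: dict
    paths: dict[str, Path] = field(default_factory=dict)


# ------------------------------------------------------------------ pipeline

def run_pipeline(
    config: PipelineConfig,
    expression: ExpressionMatrix | None = None,
    clinical: ClinicalTable | None = None,
) -> PipelineResult:
    """Preprocess → outlier replacement → signature → penalized Cox →
    stratification → evaluation, writing every artifact under the output
    directory. Inputs may be given in memory or via the config paths.
    """
    t0 = _time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if expression is None:
        expression = read_expression(config.expression_path)
    if clinical is None:
        clinical = read_clinical(config.clinical_path)
    clinical = clinical.aligned_to(expression.sample_ids)
    log.info("loaded %d probes x %d samples", *expression.shape)

    # --- preprocessing
    m = expression
    if config.quantile and m.state == "raw":
        m = quantile_normalize(m)
    if config.log_transform == "log2":
        m = log2_and_baseline(m)
    elif config.log_transform == "median":
        m = median_baseline(m if m.state != "raw" else m.with_state("normalized"))

    # --- robust outlier replacement within survival groups (labelled samples)
    classes = clinical.survival_class()
    labelled = classes.dropna().index.tolist()
    oc = OutlierConfig(seed=stage_seed(config.seed, "outliers"),
                       **config.outlier)
    sub = m.with_values(m.values[labelled], state=m.state)
    cleaned_sub, estimates, report = detect_and_replace(sub, classes.loc[labelled], oc)
    values = m.values.copy()
    values[labelled] = cleaned_sub.values
    m = m.with_values(values, state=m.state)
    log.info("flagged %.3f%% of labelled observations as contaminated",
             100 * report.fraction_contaminated)

    # --- permutation-intersection signature
    scheme = SplitScheme(n_rounds=config.n_rounds,
                         seed=stage_seed(config.seed, "signature"))
    sig = permutation_signature(
        m.with_values(m.values[labelled], state=m.state), classes.loc[labelled],
        scheme, top_k=min(config.top_k, m.shape[0]),
        freq_threshold=config.freq_threshold,
        sam_permutations=config.sam_permutations)
    log.info("signature: %d genes", len(sig.genes))

    # --- penalized Cox on Z-scored signature expression, all samples
    metrics: dict = {"n_signature_genes": len(sig.genes),
                     "fraction_contaminated": report.fraction_contaminated}
    model, strat = None, None
    if sig.genes:
        z = z_transform(m.subset_probes(sig.genes))
        data = SurvivalData(clinical.time, clinical.event,
                            z.values.T.loc[expression.sample_ids])
        pc = PenaltyConfig(seed=stage_seed(config.seed, "penalty"),
                           **config.penalty)
        model = tune_penalties_cvl(data, pc)
        scores = risk_scores(model, z)
        strat = stratify_by_median(scores)
        model.cutoff = strat.cutoff
        strat = evaluate_stratification(strat, clinical.time, clinical.event)
        metrics.update({
            "lambda1": model.lambda1, "lambda2": model.lambda2,
            "cvl": model.cvl, "cutoff": model.cutoff,
            "lrt_statistic": strat.lrt.statistic, "lrt_p": strat.lrt.p,
            "hazard_ratio": strat.lrt.hazard_ratio,
        })
        # classifier quality of high/low vs poor/good on labelled samples
        lab = strat.labels.loc[labelled]
        truth = classes.loc[labelled]
        cc = ConfusionCounts(
            tp=int(((lab == "high") & (truth == "poor")).sum()),
            fn=int(((lab == "low") & (truth == "poor")).sum()),
            tn=int(((lab == "low") & (truth == "good")).sum()),
            fp=int(((lab == "high") & (truth == "good")).sum()),
        )
        sens, spec = classification_metrics(cc)
        metrics.update({"sensitivity_pct": sens, "specificity_pct": spec,
                        "positive_class": "poor"})
        metrics["fold_changes"] = {
            g: dict(zip(("fold_change", "direction"),
                        fold_change(m.with_values(m.values[labelled], state=m.state),
                                    classes.loc[labelled], g)))
            for g in sig.genes}

    # --- outputs
    paths = {}
    paths["signature"] = write_signature(sig, out / "signature.tsv")
    report.replacements.to_csv(out / "outliers.tsv", sep="\t", index=False,
                               float_format="%.10g")
    (out / "outlier_summary.json").write_text(json.dumps({
        "fraction_contaminated": report.fraction_contaminated,
        "beta": oc.beta, "threshold": oc.weight_threshold}, sort_keys=True))
    paths["outliers"] = out / "outliers.tsv"
    if model is not None:
        paths["model"] = write_model(model, out / "model.json")
        sdf = pd.DataFrame({"sample_id": strat.scores.index,
                            "score": strat.scores.to_numpy(),
                            "group": strat.labels.to_numpy()})
        sdf.to_csv(out / "stratification.tsv", sep="\t", index=False,
                   float_format="%.10g")
        paths["stratification"] = out / "stratification.tsv"
        km_rows = []
        for gname, curve in strat.km.items():
            km_rows.append(curve.assign(group=gname))
        pd.concat(km_rows).to_csv(out / "km_curves.tsv", sep="\t", index=False,
                                  float_format="%.8g")
        paths["km"] = out / "km_curves.tsv"
    (out / "metrics.json").write_text(json.dumps(metrics, indent=1, sort_keys=True,
                                                 default=float))
    paths["metrics"] = out / "metrics.json"
    cfg_echo = asdict(config)
    cfg_echo["stage_seeds"] = {s: stage_seed(config.seed, s)
                               for s in ("outliers", "signature", "penalty")}
    cfg_echo["runtime_s"] = round(_time.time() - t0, 2)
    (out / "run_log.json").write_text(json.dumps(cfg_echo, indent=1, sort_keys=True))
    paths["log"] = out / "run_log.json"
    return PipelineResult(signature=sig, model=model, stratification=strat,
                          outlier_report=report, metrics=metrics, paths=paths)
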