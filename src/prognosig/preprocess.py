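"""Normalization chain: quantile normalization, log2 + median-baseline
transformation, and per-gene Z-transformation.

Each operation checks and advances the matrix processing state so the
chain can only be applied in order raw → normalized → baselined → zscored.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .containers import DataError, ExpressionMatrix, ParameterError


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common (mean) quantile distribution.

    After normalization every column's sorted values equal the across-sample
    mean of sorted columns. Ties within a column receive the mean of the
    reference quantiles they span, so the operation is idempotent and
    preserves within-sample rank order.
    """
    m.require_state("raw")
    x = m.to_numpy()
    if not np.all(np.isfinite(x)):
        raise DataError("quantile normalization requires finite values")
    n_genes, n_samples = x.shape
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        order = np.argsort(x[:, j], kind="mergesort")
        col = np.empty(n_genes)
        col[order] = ref
        # tied input values share the mean of their assigned reference values
        s = pd.Series(col).groupby(pd.Series(x[:, j])).transform("mean")
        out[:, j] = s.to_numpy()
    return m.with_values(
        pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        state="normalized",
    )


def log2_and_baseline(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2-transform, then center each gene at its median across samples."""
    m.require_state("raw", "normalized")
    x = m.to_numpy()
    if np.any(x <= 0):
        bad = m.values.index[(x <= 0).any(axis=1)].tolist()
        raise DataError(f"nonpositive values for probes {bad[:10]}")
    lx = np.log2(x)
    lx -= np.median(lx, axis=1, keepdims=True)
    return m.with_values(
        pd.DataFrame(lx, index=m.values.index, columns=m.values.columns),
        state="baselined",
    )


def median_baseline(m: ExpressionMatrix) -> ExpressionMatrix:
    """Median-center each gene of an already log-scale matrix."""
    m.require_state("raw", "normalized")
    x = m.to_numpy()
    x = x - np.median(x, axis=1, keepdims=True)
    return m.with_values(
        pd.DataFrame(x, index=m.values.index, columns=m.values.columns),
        state="baselined",
    )


def z_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene to mean 0 and SD 1 (denominator n−1).

    Zero-variance genes become all-zero rows and are reported in a warning
    rather than aborting, so flat probes in external cohorts do not block
    risk scoring.
    """
    if m.shape[1] < 2:
        raise ParameterError("z_transform requires at least 2 samples")
    m.require_state("raw", "normalized", "baselined")
    x = m.to_numpy()
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    flat = (sd[:, 0] == 0)
    sd[flat] = 1.0
    z = (x - mean) / sd
    z[flat] = 0.0
    if flat.any():
        names = m.values.index[flat].tolist()
        warnings.warn(f"zero-variance genes set to zeros: {names[:10]}"
                      + ("..." if flat.sum() > 10 else ""))
    return m.with_values(
        pd.DataFrame(z, index=m.values.index, columns=m.values.columns),
        state="zscored",
    )
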