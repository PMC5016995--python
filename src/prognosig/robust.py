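"""Minimum β-divergence outlier diagnosis and replacement.

Gross errors in expression data (hybridization and image artifacts) wreck
classical per-gene means and variances. The minimum β-divergence estimator
down-weights each observation by

    ψ_β(x | μ, σ) = exp(−(β/2) · ((x − μ)/σ)²),

iterating a ψ-weighted mean and a (β+1)-rescaled ψ-weighted variance to a
fixed point. Observations whose converged weight falls below a threshold
(default 0.2, i.e. |z| beyond √(2·ln 5 / β) ≈ 4.01 SDs at β = 0.2) are
flagged as contaminated and replaced by a draw from the 90% robust
confidence interval μ̂ ± 1.644·σ̂/√n of their group mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DataError, ExpressionMatrix, ParameterError

_MAD_SCALE = 1.4826  # consistency factor for Gaussian data


@dataclass(frozen=True)
class OutlierConfig:
    """Tuning of the β-divergence diagnosis.

    beta : divergence tuning parameter (> 0). Larger β down-weights
        moderate residuals more aggressively; 0.2 flags beyond ≈ 4 SD.
    weight_threshold : flag observations with ψ below this (default 0.2).
    rci_multiplier : half-width multiplier of the 90% robust CI (1.644).
    replacement : 'uniform' draws the replacement uniformly inside the rCI
        (seeded); 'mean' uses the robust mean deterministically.
    """

    beta: float = 0.2
    weight_threshold: float = 0.2
    rci_multiplier: float = 1.644
    max_iter: int = 100
    tol: float = 1e-8
    seed: int = 0
    replacement: str = "uniform"

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ParameterError("beta must be > 0")
        if not 0 < self.weight_threshold < 1:
            raise ParameterError("weight_threshold must be in (0, 1)")
        if self.rci_multiplier <= 0:
            raise ParameterError("rci_multiplier must be > 0")
        if self.replacement not in ("uniform", "mean"):
            raise ParameterError("replacement must be 'uniform' or 'mean'")


@dataclass
class BetaEstimate:
    """Converged robust estimates for one gene in one group."""

    mu: float
    sigma2: float
    weights: np.ndarray
    n_iter: int
    converged: bool


@dataclass
class RobustGroupEstimates:
    """Per-gene robust estimates for each group.

    mu / sigma2: DataFrames indexed by probe, one column per group.
    weights: per-group DataFrame of ψ values (probes × group samples).
    """

    mu: pd.DataFrame
    sigma2: pd.DataFrame
    weights: dict[str, pd.DataFrame] = field(repr=False)
    n_iter: dict[str, int] = field(default_factory=dict)
    converged: pd.DataFrame | None = field(default=None, repr=False)


@dataclass
class OutlierReport:
    mask: pd.DataFrame = field(repr=False)  # bool, probes × samples
    fraction_contaminated: float = 0.0
    replacements: pd.DataFrame = field(default=None, repr=False)
    rci_bounds: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)


def beta_weight(x, mu, sigma, beta: float):
    """ψ_β weight of an observation: exp(−(β/2)·((x−μ)/σ)²)."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ParameterError("sigma must be > 0")
    if beta <= 0:
        raise ParameterError("beta must be > 0")
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return np.exp(-0.5 * beta * z * z)


def flag_z_threshold(beta: float, weight_threshold: float = 0.2) -> float:
    """|z| beyond which ψ_β drops below the flag threshold."""
    return float(np.sqrt(-2.0 * np.log(weight_threshold) / beta))


def _fit_matrix(x: np.ndarray, config: OutlierConfig, active: np.ndarray | None = None):
    """Vectorized fixed-point iteration over genes (rows of ``x``).

    ``active`` (same shape, boolean) restricts the fit to a subset of
    observations per gene; weights are still reported for every
    observation. Returns (mu, sigma2, weights, n_iter, converged). Both
    updates use the weights and mean of the previous iterate; convergence
    is measured as max(|Δμ|, |Δσ²|) relative to σ̂².
    """
    x = np.asarray(x, dtype=float)
    g, n = x.shape
    if n < 3:
        raise ParameterError("need at least 3 observations per group")
    if not np.all(np.isfinite(x)):
        raise DataError("non-finite values in robust fit")
    if active is None:
        active = np.ones_like(x, dtype=bool)
    if (active.sum(axis=1) < 3).any():
        raise ParameterError("need at least 3 retained observations per group")

    xa = np.where(active, x, np.nan)
    mu = np.nanmedian(xa, axis=1)
    mad = np.nanmedian(np.abs(xa - mu[:, None]), axis=1)
    sd0 = _MAD_SCALE * mad
    fallback = sd0 == 0
    if fallback.any():
        sd0 = np.where(fallback, np.nanstd(xa, axis=1, ddof=0), sd0)
    degenerate = sd0 == 0
    if degenerate.any():
        raise DataError(
            "degenerate variance (all-identical values) for gene rows "
            f"{np.flatnonzero(degenerate)[:10].tolist()}"
        )
    sigma2 = sd0**2

    n_iter = 0
    converged = np.zeros(g, dtype=bool)
    for it in range(1, config.max_iter + 1):
        z2 = (x - mu[:, None]) ** 2 / sigma2[:, None]
        w = np.exp(-0.5 * config.beta * z2) * active
        sw = w.sum(axis=1)
        mu_new = (w * x).sum(axis=1) / sw
        resid2 = (x - mu[:, None]) ** 2
        sigma2_new = (config.beta + 1.0) * (w * resid2).sum(axis=1) / sw
        delta = np.maximum(np.abs(mu_new - mu), np.abs(sigma2_new - sigma2))
        converged = delta < config.tol * sigma2_new
        mu, sigma2 = mu_new, sigma2_new
        n_iter = it
        if converged.all():
            break
    z2 = (x - mu[:, None]) ** 2 / sigma2[:, None]
    weights = np.exp(-0.5 * config.beta * z2)
    return mu, sigma2, weights, n_iter, converged


def fit_beta_estimators(values, config: OutlierConfig | None = None) -> BetaEstimate:
    """Robust mean/variance for one gene's expressions in one group."""
    config = config or OutlierConfig()
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ParameterError("values must be one-dimensional")
    mu, sigma2, w, n_iter, conv = _fit_matrix(values[None, :], config)
    if not conv[0]:
        import warnings

        warnings.warn(f"beta estimator did not converge in {config.max_iter} iterations")
    return BetaEstimate(float(mu[0]), float(sigma2[0]), w[0], n_iter, bool(conv[0]))


def robust_ci(mu, sigma2, n: int, config: OutlierConfig | None = None):
    """90% robust confidence interval μ̂ ± multiplier·σ̂/√n for the group mean."""
    config = config or OutlierConfig()
    if n < 1:
        raise ParameterError("n must be >= 1")
    half = config.rci_multiplier * np.sqrt(np.asarray(sigma2, dtype=float)) / np.sqrt(n)
    mu = np.asarray(mu, dtype=float)
    return mu - half, mu + half


def _initial_screen(xg: np.ndarray, config: OutlierConfig) -> np.ndarray:
    """Candidate flags from ψ at the median / 1.4826·MAD starting point."""
    mu0 = np.median(xg, axis=1)
    mad = np.median(np.abs(xg - mu0[:, None]), axis=1)
    sd0 = _MAD_SCALE * mad
    zero = sd0 == 0
    if zero.any():
        sd0 = np.where(zero, xg.std(axis=1, ddof=0), sd0)
    sd0[sd0 == 0] = np.inf  # constant gene: nothing to screen
    w0 = np.exp(-0.5 * config.beta * ((xg - mu0[:, None]) / sd0[:, None]) ** 2)
    return _cap_flags(w0 < config.weight_threshold, w0, min_keep=3)


def _cap_flags(flags: np.ndarray, w: np.ndarray, min_keep: int) -> np.ndarray:
    """Unflag the highest-weight observations where too few would remain."""
    n = flags.shape[1]
    over = np.flatnonzero(n - flags.sum(axis=1) < min_keep)
    for g in over:
        keep = np.argsort(w[g])[::-1][:min_keep]
        flags[g, keep] = False
    return flags


def detect_and_replace(
    m: ExpressionMatrix,
    groups,
    config: OutlierConfig | None = None,
) -> tuple[ExpressionMatrix, RobustGroupEstimates, OutlierReport]:
    """Flag and replace contaminated observations per gene and group.

    ``groups`` maps every sample id to one of two group labels. Within each
    gene × group cell the β-estimators are fitted and observations with
    ψ < weight_threshold are flagged; the diagnosis then iterates — the
    estimators are refit on the retained observations until the flag set
    stabilizes — so a cluster of gross errors cannot hide by inflating the
    scale estimate. Each flagged value is finally replaced (uniform draw
    inside the group's rCI by default, or the robust mean). The flag mask
    does not depend on the replacement seed.
    """
    config = config or OutlierConfig()
    groups = pd.Series(groups)
    if set(m.sample_ids) <= set(groups.index):
        groups = groups.loc[m.sample_ids]
    elif len(groups) == m.shape[1]:
        groups.index = m.sample_ids
    else:
        raise ParameterError("every sample needs a group label")
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ParameterError(f"expected exactly two groups, got {labels}")

    x = m.to_numpy()
    out = x.copy()
    probes, samples = m.values.index, m.values.columns
    rng = np.random.default_rng(config.seed)

    mu_df = pd.DataFrame(index=probes, columns=labels, dtype=float)
    s2_df = pd.DataFrame(index=probes, columns=labels, dtype=float)
    conv_df = pd.DataFrame(index=probes, columns=labels, dtype=bool)
    weights, n_iters, bounds = {}, {}, {}
    mask = np.zeros_like(x, dtype=bool)
    repl_rows = []

    for lab in labels:
        idx = np.flatnonzero((groups == lab).to_numpy())
        if len(idx) < 3:
            raise ParameterError(f"group {lab!r} has fewer than 3 samples")
        xg = x[:, idx]
        # screen candidate gross errors at the robust initialization so a
        # cluster cannot hide by inflating the converged scale estimate
        active = ~_initial_screen(xg, config)
        flags = ~active
        for _ in range(20):
            mu, s2, w, n_iter, conv = _fit_matrix(xg, config, active)
            flags = w < config.weight_threshold
            flags = _cap_flags(flags, w, min_keep=3)
            if (~flags == active).all():
                break
            active = ~flags
        mu_df[lab], s2_df[lab], conv_df[lab] = mu, s2, conv
        weights[lab] = pd.DataFrame(w, index=probes, columns=samples[idx])
        n_iters[lab] = n_iter
        low, high = robust_ci(mu, s2, len(idx), config)
        bounds[lab] = pd.DataFrame({"low": low, "high": high}, index=probes)
        gi, ki = np.nonzero(flags)
        cols = idx[ki]
        mask[gi, cols] = True
        if config.replacement == "uniform":
            new = low[gi] + rng.random(len(gi)) * (high[gi] - low[gi])
        else:
            new = mu[gi]
        for r, (g_row, c, v) in enumerate(zip(gi, cols, new)):
            repl_rows.append((probes[g_row], samples[c], lab,
                              float(x[g_row, c]), float(v), float(w[g_row, ki[r]])))
        out[gi, cols] = new

    est = RobustGroupEstimates(mu=mu_df, sigma2=s2_df, weights=weights,
                               n_iter=n_iters, converged=conv_df)
    report = OutlierReport(
        mask=pd.DataFrame(mask, index=probes, columns=samples),
        fraction_contaminated=float(mask.sum()) / mask.size,
        replacements=pd.DataFrame(
            repl_rows, columns=["gene", "sample", "group", "old", "new", "weight"]
        ),
        rci_bounds=bounds,
    )
    cleaned = m.with_values(pd.DataFrame(out, index=probes, columns=samples),
                            state=m.state)
    return cleaned, est, report
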