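"""Permutation-intersection selection of a differential-expression signature.

The cohort's class-labelled samples are split 100 times into stratified
train/test halves of equal size. Within each half three statistics are
computed per gene — Welch t, a SAM-style statistic with fudge factor s₀
and pooled permutation p-values, and an empirical-Bayes moderated t — and
the top-k genes of each method (by Benjamini–Hochberg adjusted p) are
intersected across methods and then across the two halves. Genes present
in at least a threshold fraction of rounds form the signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .containers import ParameterError

METHODS = ("t", "sam", "modt")


@dataclass(frozen=True)
class SplitScheme:
    """Repeated stratified half-splits of the class-labelled samples."""

    n_rounds: int = 100
    seed: int = 0
    with_replacement: bool = False  # bootstrap halves instead of a partition

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ParameterError("n_rounds must be >= 1")

    def make_splits(self, classes: pd.Series) -> list[tuple[list, list]]:
        """Per-round (train ids, test ids), stratified by class.

        Classes with an odd count donate their leftover sample alternately
        to train and test so the halves stay equal within one sample.
        """
        classes = classes.dropna()
        rng = np.random.default_rng(self.seed)
        by_class = {c: classes.index[classes == c].to_numpy()
                    for c in sorted(classes.unique())}
        splits = []
        for _ in range(self.n_rounds):
            train, test = [], []
            side = rng.integers(0, 2)
            for ids in by_class.values():
                if self.with_replacement:
                    half = len(ids) // 2
                    train.extend(rng.choice(ids, size=half, replace=True))
                    test.extend(rng.choice(ids, size=half, replace=True))
                    continue
                perm = rng.permutation(ids)
                half = len(ids) // 2
                train.extend(perm[:half])
                test.extend(perm[half: 2 * half])
                if len(ids) % 2:
                    (train if side else test).append(perm[-1])
                    side = 1 - side
            splits.append((sorted(train), sorted(test)))
        return splits


@dataclass
class GeneSignature:
    """Selected genes with per-round survival frequencies."""

    genes: list[str]
    frequency: pd.Series = field(repr=False)  # over every gene seen in any round
    top_k: int = 0
    freq_threshold: float = 0.95
    n_rounds: int = 0


def _group_arrays(x: np.ndarray, is_g1: np.ndarray):
    return x[:, is_g1], x[:, ~is_g1]


def _pooled_sd(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """SAM's gene-wise scatter: sqrt{(1/n1+1/n2)·(ss1+ss2)/(n1+n2−2)}."""
    n1, n2 = x1.shape[1], x2.shape[1]
    ss1 = ((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss2 = ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * (ss1 + ss2) / (n1 + n2 - 2))


def sam_fudge_factor(s: np.ndarray, mode: str = "median") -> float:
    """Fudge factor s₀ stabilizing small variances (default: median of s_i)."""
    if mode == "median":
        return float(np.median(s))
    if mode == "tusher":
        # pick the percentile of s minimizing the coefficient of variation of
        # the d-statistic spread across s-quantile windows (coarse search)
        return _tusher_s0(s)
    raise ParameterError(f"unknown s0 mode {mode!r}")


def _tusher_s0(s: np.ndarray) -> float:
    qs = np.percentile(s, np.arange(0, 101, 5))
    cvs = []
    for s0 in qs:
        scaled = s / (s + s0)
        windows = np.array_split(np.sort(scaled), 10)
        mads = [np.median(np.abs(w - np.median(w))) for w in windows if len(w)]
        cvs.append(np.std(mads) / np.mean(mads) if np.mean(mads) > 0 else np.inf)
    return float(qs[int(np.argmin(cvs))])


def _sam_statistic(x: np.ndarray, is_g1: np.ndarray, s0: float) -> np.ndarray:
    x1, x2 = _group_arrays(x, is_g1)
    s = _pooled_sd(x1, x2)
    return (x1.mean(axis=1) - x2.mean(axis=1)) / (s + s0)


def _sam(x, is_g1, n_permutations, rng, s0_mode):
    x1, x2 = _group_arrays(x, is_g1)
    s = _pooled_sd(x1, x2)
    s0 = sam_fudge_factor(s, s0_mode)
    d = _sam_statistic(x, is_g1, s0)

    # permutation null, pooled across genes: group sums under label shuffles
    # computed as matrix products with a membership matrix
    n = x.shape[1]
    n1 = int(is_g1.sum())
    members = np.zeros((n, n_permutations))
    for p in range(n_permutations):
        members[rng.permutation(n)[:n1], p] = 1.0
    xs, xq = x, x**2
    tot, qtot = xs.sum(axis=1, keepdims=True), xq.sum(axis=1, keepdims=True)
    s1, q1 = xs @ members, xq @ members
    s2, q2 = tot - s1, qtot - q1
    n2 = n - n1
    m1, m2 = s1 / n1, s2 / n2
    ss1 = q1 - n1 * m1**2
    ss2 = q2 - n2 * m2**2
    sp = np.sqrt((1.0 / n1 + 1.0 / n2) * np.maximum(ss1 + ss2, 0.0) / (n - 2))
    d_null = np.abs((m1 - m2) / (sp + s0)).ravel()
    d_null.sort()
    exceed = len(d_null) - np.searchsorted(d_null, np.abs(d), side="left")
    p = (exceed + 1.0) / (len(d_null) + 1.0)
    return d, p


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderated_t(x: np.ndarray, is_g1: np.ndarray):
    """Empirical-Bayes moderated t with method-of-moments variance prior.

    Per-gene pooled variances are shrunk toward a prior s₀² with d₀ prior
    degrees of freedom estimated from the spread of log residual variances;
    the moderated t uses d₀ + d residual degrees of freedom.
    """
    x1, x2 = _group_arrays(x, is_g1)
    n1, n2 = x1.shape[1], x2.shape[1]
    d = n1 + n2 - 2
    ss = (((x1 - x1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
          + ((x2 - x2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))
    s2 = np.maximum(ss / d, 1e-300)

    e = np.log(s2) - special.digamma(d / 2.0) + np.log(d / 2.0)
    var_e = float(np.var(e, ddof=1)) if len(e) > 1 else 0.0
    excess = var_e - float(special.polygamma(1, d / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s02 = np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0, s02 = np.inf, float(np.exp(np.mean(e)))

    if np.isfinite(d0):
        s2_tilde = (d0 * s02 + d * s2) / (d0 + d)
        df = d0 + d
    else:
        s2_tilde = np.full_like(s2, s02)
        df = 1e6
    tstat = (x1.mean(axis=1) - x2.mean(axis=1)) / np.sqrt(
        s2_tilde * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=df)
    return tstat, p


def compute_de_statistics(
    m,
    classes,
    method: str,
    *,
    sam_permutations: int = 500,
    sam_s0: str = "median",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene differential-expression statistics for one method.

    ``classes`` gives a good/poor label per sample of ``m`` (Series indexed
    by sample id, or aligned array). Returns a DataFrame indexed by probe
    with columns ``statistic``, ``p``, ``p_adj`` (Benjamini–Hochberg) and
    ``method``.
    """
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r}; expected one of {METHODS}")
    x = m.to_numpy() if hasattr(m, "to_numpy") else np.asarray(m, dtype=float)
    probes = m.values.index if hasattr(m, "values") else pd.RangeIndex(x.shape[0])
    classes = pd.Series(classes)
    if hasattr(m, "sample_ids") and set(m.sample_ids) <= set(classes.index):
        classes = classes.loc[m.sample_ids]
    labels = sorted(classes.dropna().unique())
    if len(labels) != 2:
        raise ParameterError(f"need exactly two classes, got {labels}")
    is_g1 = (classes == labels[0]).to_numpy()
    if is_g1.sum() < 2 or (~is_g1).sum() < 2:
        raise ParameterError("each class needs at least 2 samples")
    if np.isnan(x).any():
        raise ParameterError("missing values not allowed")

    if method == "t":
        x1, x2 = _group_arrays(x, is_g1)
        res = stats.ttest_ind(x1, x2, axis=1, equal_var=False)
        stat, p = res.statistic, res.pvalue
    elif method == "sam":
        rng = np.random.default_rng(seed)
        stat, p = _sam(x, is_g1, sam_permutations, rng, sam_s0)
    else:
        stat, p = moderated_t(x, is_g1)

    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"statistic": stat, "p": p, "p_adj": p_adj, "method": method}, index=probes
    )


def select_top_k(result: pd.DataFrame, k: int) -> list[str]:
    """The k genes with smallest adjusted p.

    Ties broken by larger |statistic|, then lexicographic probe id, so the
    selection is deterministic.
    """
    if k <= 0:
        raise ParameterError("k must be >= 1")
    if k > len(result):
        raise ParameterError(f"k={k} exceeds gene count {len(result)}")
    order = result.assign(
        _abs=-result["statistic"].abs(), _id=result.index.astype(str)
    ).sort_values(["p_adj", "_abs", "_id"], kind="mergesort")
    return order.index[:k].tolist()


def permutation_signature(
    m,
    classes,
    scheme: SplitScheme | None = None,
    top_k: int = 1500,
    freq_threshold: float = 0.95,
    *,
    sam_permutations: int = 500,
    sam_s0: str = "median",
) -> GeneSignature:
    """Run the full split–test–intersect scheme and return the signature.

    Per round: split the labelled samples into stratified train/test
    halves; in each half run all three statistics, take each method's
    top-k genes, intersect across methods, then intersect the train and
    test survivor sets. The signature is every gene whose round-set
    membership frequency reaches ``freq_threshold``, ordered by frequency
    (descending) then id.
    """
    scheme = scheme or SplitScheme()
    classes = pd.Series(classes).dropna()
    classes = classes[classes.astype(str) != "NA"]
    splits = scheme.make_splits(classes)
    seed_seq = np.random.SeedSequence(scheme.seed)
    round_seeds = seed_seq.generate_state(2 * len(splits))

    counts: dict[str, int] = {}
    for r, (train, test) in enumerate(splits):
        survivors = None
        for h, ids in enumerate((train, test)):
            sub = m.values[ids] if hasattr(m, "values") else None
            subm = m.with_values(sub, state=m.state) if sub is not None else m
            half_sets = []
            for method in METHODS:
                res = compute_de_statistics(
                    subm, classes.loc[ids], method,
                    sam_permutations=sam_permutations, sam_s0=sam_s0,
                    seed=int(round_seeds[2 * r + h] % (2**31)),
                )
                half_sets.append(set(select_top_k(res, min(top_k, len(res)))))
            half_common = set.intersection(*half_sets)
            survivors = half_common if survivors is None else survivors & half_common
        for gene in survivors:
            counts[gene] = counts.get(gene, 0) + 1

    freq = pd.Series(counts, dtype=float) / scheme.n_rounds
    freq = freq.sort_values(ascending=False)
    selected = freq[freq >= freq_threshold]
    genes = sorted(selected.index, key=lambda g: (-selected[g], str(g)))
    if not genes:
        warnings.warn("empty signature: no gene reached the frequency threshold")
    return GeneSignature(genes=genes, frequency=freq, top_k=top_k,
                         freq_threshold=freq_threshold, n_rounds=scheme.n_rounds)
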