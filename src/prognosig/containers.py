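"""Core data containers shared across the pipeline.

An :class:`ExpressionMatrix` is a probes × samples grid of intensities with a
processing-state tag that lets downstream stages refuse out-of-order input
(e.g. quantile normalization of already-normalized data). A
:class:`ClinicalTable` holds per-sample survival follow-up and covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Processing states, in pipeline order.
STATES = ("raw", "normalized", "baselined", "zscored")

VALID_CLASSES = ("good", "poor")
VALID_STAGES = ("B", "C")
VALID_GENDERS = ("M", "F")


class ParameterError(ValueError):
    """A configuration or argument value violates its contract."""


class DataError(ValueError):
    """Input data violate a precondition (non-finite, nonpositive, degenerate)."""


class ConvergenceError(RuntimeError):
    """An iterative fit failed to converge or diverged."""


class AlignmentError(ValueError):
    """Sample identifiers of two inputs do not correspond."""


@dataclass
class ExpressionMatrix:
    """Probes × samples expression grid.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by probe id, columns by sample id; numeric.
    state : str
        One of :data:`STATES`; tracks how far through the normalization
        chain the values have travelled.
    """

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ParameterError(f"unknown state {self.state!r}; expected one of {STATES}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise DataError(f"duplicate probe ids: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise DataError("expression values must be numeric")
        if self.state != "raw" and not np.all(np.isfinite(arr)):
            raise DataError(f"non-finite values not allowed in state {self.state!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def with_values(self, values: pd.DataFrame, state: str) -> "ExpressionMatrix":
        return ExpressionMatrix(values=values, state=state)

    def with_state(self, state: str) -> "ExpressionMatrix":
        """Re-tag the processing state (e.g. data already on the log scale)."""
        return replace(self, state=state)

    def require_state(self, *allowed: str) -> None:
        if self.state not in allowed:
            raise DataError(
                f"operation requires state in {allowed}, got {self.state!r}"
            )

    def subset_probes(self, probe_ids) -> "ExpressionMatrix":
        missing = [p for p in probe_ids if p not in self.values.index]
        if missing:
            raise KeyError(f"probes absent from matrix: {missing[:10]}")
        return replace(self, values=self.values.loc[list(probe_ids)])


REQUIRED_CLINICAL_COLUMNS = ("sample_id", "time_months", "event")
OPTIONAL_CLINICAL_COLUMNS = ("class", "stage", "age", "gender")


@dataclass
class ClinicalTable:
    """Per-sample survival annotation.

    Columns: ``sample_id``, ``time_months`` (> 0), ``event`` (1 = death,
    0 = censored/alive), and optionally ``class`` (good/poor five-year
    survival group), ``stage`` (Dukes' B/C), ``age``, ``gender`` (M/F).
    Missing categorical entries are NA.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        for col in REQUIRED_CLINICAL_COLUMNS:
            if col not in t.columns:
                raise DataError(f"clinical table missing required column {col!r}")
        if t["sample_id"].duplicated().any():
            dups = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise DataError(f"duplicate sample ids: {dups[:5]}")
        time = pd.to_numeric(t["time_months"], errors="coerce")
        if time.isna().any() or (time <= 0).any():
            bad = t.loc[time.isna() | (time <= 0), "sample_id"].tolist()
            raise DataError(f"time_months must be positive for samples {bad[:5]}")
        event = pd.to_numeric(t["event"], errors="coerce")
        if not event.isin([0, 1]).all():
            bad = t.loc[~event.isin([0, 1]), "sample_id"].tolist()
            raise DataError(f"event must be 0 or 1 for samples {bad[:5]}")
        for col, valid in (("class", VALID_CLASSES), ("stage", VALID_STAGES),
                           ("gender", VALID_GENDERS)):
            if col in t.columns:
                vals = t[col].dropna()
                vals = vals[vals.astype(str) != "NA"]
                bad = vals[~vals.isin(valid)]
                if len(bad):
                    raise DataError(f"invalid {col} values: {sorted(set(bad))[:5]}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def time(self) -> np.ndarray:
        return self.table["time_months"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.table["event"].to_numpy(dtype=int)

    def survival_class(self) -> pd.Series:
        """Good/poor labels indexed by sample id (NA where unassigned)."""
        t = self.table
        cls = t["class"] if "class" in t.columns else pd.Series(pd.NA, index=t.index)
        cls = cls.where(cls.astype(str) != "NA", pd.NA)
        return pd.Series(cls.to_numpy(), index=t["sample_id"].to_numpy(), name="class")

    def aligned_to(self, sample_ids) -> "ClinicalTable":
        """Reorder rows to the given sample ids; error on mismatch."""
        t = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in t.index]
        extra = [s for s in t.index if s not in set(sample_ids)]
        if missing or extra:
            raise AlignmentError(
                f"sample-id mismatch: missing from clinical {missing[:5]}, "
                f"unmatched clinical rows {extra[:5]}"
            )
        return ClinicalTable(t.loc[list(sample_ids)].reset_index())


def derive_survival_class(time_months: np.ndarray, event: np.ndarray,
                          horizon: float = 60.0) -> np.ndarray:
    """Five-year survival grouping.

    good  = survived at least `horizon` months (event or not);
    poor  = died before `horizon`;
    NA    = censored before `horizon` (follow-up too short to classify).
    """
    time_months = np.asarray(time_months, dtype=float)
    event = np.asarray(event, dtype=int)
    out = np.where(time_months >= horizon, "good",
                   np.where(event == 1, "poor", "NA"))
    return out.astype(object)
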