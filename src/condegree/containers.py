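"""Core data containers shared by every analysis stage.

An :class:`ExpressionMatrix` is a genes x samples real matrix with string
identifiers (microarray convention: genes in rows).  A :class:`ClinicalTable`
wraps a per-sample data frame together with a declaration of which columns
hold binary endpoint labels and which hold survival time / event status.
Both validate their invariants on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "PerformanceTable",
    "ErrorRateTable",
    "align",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValidationError(f"duplicate {what} identifier: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Gene x sample expression matrix.

    Values are taken as-is (assumed already normalised / log-scaled upstream);
    missing values are rejected rather than imputed.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D matrix")
        ng, ns = self.values.shape
        if ng != len(self.gene_ids):
            raise ValidationError(
                f"row count {ng} != number of gene ids {len(self.gene_ids)}"
            )
        if ns != len(self.sample_ids):
            raise ValidationError(
                f"column count {ns} != number of sample ids {len(self.sample_ids)}"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite expression value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=np.float64))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing[:5]}")
        cols = [pos[s] for s in ids]
        return ExpressionMatrix(list(self.gene_ids), list(ids), self.values[:, cols])

    def subset_genes(self, ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: k for k, g in enumerate(self.gene_ids)}
        missing = [g for g in ids if g not in pos]
        if missing:
            raise ValidationError(f"unknown gene ids: {missing[:5]}")
        rows = [pos[g] for g in ids]
        return ExpressionMatrix(list(ids), list(self.sample_ids), self.values[rows, :])


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations.

    ``data`` is indexed by sample id.  ``endpoint_cols`` lists columns holding
    binary endpoint labels (0/1, missing as NaN).  ``time_col``/``event_col``
    optionally name the survival time (days) and event indicator columns.
    Missing entries stay missing (NaN) — they are never silently coerced to 0.
    """

    data: pd.DataFrame
    endpoint_cols: tuple[str, ...] = ()
    time_col: str | None = None
    event_col: str | None = None

    def __post_init__(self) -> None:
        self.data = self.data.copy()
        self.data.index = self.data.index.astype(str)
        self.endpoint_cols = tuple(self.endpoint_cols)
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate sample identifier: {dup!r}")
        for col in self.endpoint_cols:
            if col not in self.data.columns:
                raise ValidationError(f"endpoint column {col!r} not present")
            vals = pd.to_numeric(self.data[col], errors="coerce")
            bad = self.data[col].notna() & vals.isna()
            if bad.any():
                raise ValidationError(
                    f"endpoint {col!r}: non-numeric label for sample "
                    f"{self.data.index[bad][0]!r}"
                )
            outside = vals.dropna()[~vals.dropna().isin([0, 1])]
            if len(outside):
                raise ValidationError(
                    f"endpoint {col!r}: label {outside.iloc[0]} outside {{0,1}}"
                )
            self.data[col] = vals
        if (self.time_col is None) != (self.event_col is None):
            raise ValidationError("time_col and event_col must be given together")
        if self.time_col is not None:
            for col in (self.time_col, self.event_col):
                if col not in self.data.columns:
                    raise ValidationError(f"survival column {col!r} not present")
            t = pd.to_numeric(self.data[self.time_col], errors="coerce")
            bad = self.data[self.time_col].notna() & t.isna()
            if bad.any():
                raise ValidationError(
                    f"non-numeric survival time for sample {self.data.index[bad][0]!r}"
                )
            if (t.dropna() < 0).any():
                s = t.dropna()[t.dropna() < 0].index[0]
                raise ValidationError(f"negative survival time for sample {s!r}")
            e = pd.to_numeric(self.data[self.event_col], errors="coerce")
            outside = e.dropna()[~e.dropna().isin([0, 1])]
            if len(outside):
                raise ValidationError(
                    f"event indicator {outside.iloc[0]} outside {{0,1}}"
                )
            if (t.notna() & e.isna()).any():
                s = self.data.index[t.notna() & e.isna()][0]
                raise ValidationError(
                    f"survival time present but event missing for sample {s!r}"
                )
            self.data[self.time_col] = t
            self.data[self.event_col] = e

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def labels(self, endpoint: str) -> pd.Series:
        """Binary labels for one endpoint (NaN = missing)."""
        if endpoint not in self.endpoint_cols:
            raise ValidationError(f"unknown endpoint {endpoint!r}")
        return self.data[endpoint]

    def survival(self, dropna: bool = True) -> tuple[pd.Series, pd.Series]:
        """(time, event) series, by default restricted to complete pairs."""
        if self.time_col is None:
            raise ValidationError("no survival columns declared")
        t = self.data[self.time_col]
        e = self.data[self.event_col]
        if dropna:
            keep = t.notna()
            t, e = t[keep], e[keep]
        return t, e


@dataclass
class PerformanceTable:
    """Per-endpoint lists of external-validation MCC values for candidate
    models (each in [-1, 1], each list non-empty)."""

    mcc: Mapping[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, list[float]] = {}
        for ep, vals in self.mcc.items():
            vals = [float(v) for v in vals]
            if not vals:
                raise ValidationError(f"endpoint {ep!r}: empty MCC list")
            for v in vals:
                if not (-1.0 <= v <= 1.0):
                    raise ValidationError(f"endpoint {ep!r}: MCC {v} outside [-1,1]")
            clean[str(ep)] = vals
        self.mcc = clean

    @property
    def endpoints(self) -> list[str]:
        return list(self.mcc)

    def top_mean(self, endpoint: str, k: int) -> float:
        vals = sorted(self.mcc[endpoint], reverse=True)[: max(1, k)]
        return float(np.mean(vals))


@dataclass
class ErrorRateTable:
    """Per-sample prediction error rate with the number of models that
    predicted the sample."""

    data: pd.DataFrame  # columns: error_rate, n_models; index: sample id

    def __post_init__(self) -> None:
        df = self.data.copy()
        df.index = df.index.astype(str)
        if df.index.has_duplicates:
            raise ValidationError("duplicate sample identifier in error-rate table")
        for col in ("error_rate", "n_models"):
            if col not in df.columns:
                raise ValidationError(f"error-rate table lacks column {col!r}")
        df["error_rate"] = pd.to_numeric(df["error_rate"])
        df["n_models"] = pd.to_numeric(df["n_models"]).astype(int)
        if ((df["error_rate"] < 0) | (df["error_rate"] > 1)).any():
            raise ValidationError("error rate outside [0, 1]")
        if (df["n_models"] < 0).any():
            raise ValidationError("negative model count")
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


def align(
    expr: ExpressionMatrix, clin: ClinicalTable, endpoint: str
) -> tuple[ExpressionMatrix, np.ndarray]:
    """Intersect samples, drop missing labels and return matched inputs.

    The output is canonical (genes and samples sorted by identifier) so it is
    invariant to the row/column order of either input.  Requires at least two
    samples per class.
    """
    labels = clin.labels(endpoint)
    labelled = set(labels.dropna().index)
    shared = sorted(set(expr.sample_ids) & labelled)
    y = np.array([int(labels[s]) for s in shared], dtype=np.int64)
    n0, n1 = int(np.sum(y == 0)), int(np.sum(y == 1))
    if n0 < 2 or n1 < 2:
        raise DegenerateInputError(
            f"endpoint {endpoint!r}: need >= 2 samples per class after alignment "
            f"(got {n0} / {n1})"
        )
    sub = expr.subset_samples(shared).subset_genes(sorted(expr.gene_ids))
    return sub, y
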