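"""Tab-delimited readers/writers and the run manifest.

All tables are plain TSV (diffable, microarray-era style).  The expression
format is genes in rows, samples in columns, first column gene id, header row
sample ids; ``transpose=True`` accepts samples-in-rows files.
"""

from __future__ import annotations

import json
import logging
import platform
import sys
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import ClinicalTable, ErrorRateTable, ExpressionMatrix, PerformanceTable
from .errors import ParseError, ValidationError

log = logging.getLogger("condegree.io")

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "read_performance_table",
    "read_error_rate_table",
    "write_manifest",
]


def read_expression_matrix(path: str | Path, transpose: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix; every cell must be numeric."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if transpose:
        df = df.T
    numeric = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            gene = df.index[bad][0]
            raise ParseError(
                f"{path}: non-numeric expression value at gene {gene!r}, sample {col!r}"
            )
        numeric[col] = vals
    return ExpressionMatrix.from_dataframe(numeric)


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    df = em.to_dataframe()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_clinical_table(
    path: str | Path,
    endpoint_cols: Sequence[str] = (),
    time_col: str | None = None,
    event_col: str | None = None,
) -> ClinicalTable:
    """Read a per-sample TSV; the column roles come from configuration.

    Empty cells are recorded as missing, never as 0.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ClinicalTable(
        df, endpoint_cols=tuple(endpoint_cols), time_col=time_col, event_col=event_col
    )


def write_clinical_table(clin: ClinicalTable, path: str | Path) -> None:
    out = clin.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_performance_table(path: str | Path) -> PerformanceTable:
    """Read a long-format TSV with columns (endpoint, mcc)."""
    df = pd.read_csv(path, sep="\t")
    if not {"endpoint", "mcc"}.issubset(df.columns):
        raise ParseError(f"{path}: expected columns 'endpoint' and 'mcc'")
    mcc: dict[str, list[float]] = {}
    for ep, grp in df.groupby("endpoint", sort=False):
        mcc[str(ep)] = [float(v) for v in grp["mcc"]]
    return PerformanceTable(mcc)


def read_error_rate_table(path: str | Path) -> ErrorRateTable:
    """Read a TSV with columns (sample_id, error_rate, n_models)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ErrorRateTable(df)


def write_manifest(path: str | Path, params: dict, seed: int | None = None) -> None:
    """Write a machine-readable record of a run (parameters, seed, versions)."""
    manifest = {
        "tool": "condegree",
        "seed": seed,
        "parameters": params,
        "versions": {
            "python": sys.version.split()[0],
            "platform": platform.platform(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    try:
        from . import __version__

        manifest["versions"]["condegree"] = __version__
    except Exception:  # pragma: no cover
        pass
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
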