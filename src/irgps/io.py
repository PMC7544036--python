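"""Reading, validation and canonicalization of expression matrices,
clinical tables, gene lists and feature tables.

Conventions
-----------
* Expression matrices are pandas DataFrames with gene symbols as the index
  (rows) and sample ids as columns, FPKM-like non-negative values.
* Clinical / survival tables are DataFrames indexed by sample id with at
  least ``os_time`` (months, > 0) and ``event`` (0/1) columns; any further
  columns are covariates and may contain missing values.
* Gene sets are plain ``set`` objects of canonicalized symbols.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "canonicalize_symbol",
    "read_expression",
    "write_expression",
    "read_clinical",
    "read_geneset",
    "read_feature_table",
    "validate_expression",
    "collapse_duplicates",
    "average_patient_samples",
    "filter_genes",
    "restrict_to_geneset",
    "mad",
]

#: clinical columns that must always be present and complete
REQUIRED_CLINICAL = ("os_time", "event")

#: accepted aliases for the mandatory clinical columns (header -> canonical)
_CLINICAL_ALIASES = {
    "os_time_months": "os_time",
    "os_months": "os_time",
    "time": "os_time",
    "status": "event",
    "os_event": "event",
}


def canonicalize_symbol(symbol: str) -> str:
    """Uppercase + strip whitespace; no alias resolution."""
    return str(symbol).strip().upper()


def _sep_for(path: str, dialect: str | None) -> str:
    if dialect is not None:
        return {"tsv": "\t", "csv": ","}[dialect]
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def validate_expression(matrix: pd.DataFrame, *, context: str = "expression matrix") -> pd.DataFrame:
    """Check the ExpressionMatrix invariants, returning the input unchanged.

    Raises ``ValueError`` on duplicate gene symbols or sample ids, empty
    axes, or any non-finite / negative / missing value.
    """
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError(f"{context}: gene and sample axes must be nonempty, got shape {matrix.shape}")
    if matrix.index.duplicated().any():
        dups = sorted(set(matrix.index[matrix.index.duplicated()]))
        raise ValueError(f"{context}: duplicate gene symbols {dups} (run collapse_duplicates first)")
    if matrix.columns.duplicated().any():
        dups = sorted(set(matrix.columns[matrix.columns.duplicated()]))
        raise ValueError(f"{context}: duplicate sample ids {dups}")
    values = matrix.to_numpy(dtype=float, na_value=np.nan)
    if np.isnan(values).any():
        raise ValueError(f"{context}: missing values are not allowed")
    if not np.isfinite(values).all():
        raise ValueError(f"{context}: non-finite values present")
    if (values < 0).any():
        raise ValueError(f"{context}: negative values present (FPKM/intensity scale expected)")
    return matrix


def read_expression(path: str, dialect: str | None = None, *, allow_duplicate_genes: bool = True) -> pd.DataFrame:
    """Read a genes x samples matrix from delimited text.

    First column holds gene/probe symbols, the header row sample ids.
    Duplicate gene rows (multi-probe genes) are allowed and left for
    :func:`collapse_duplicates`; duplicate sample ids are a hard error.
    """
    sep = _sep_for(path, dialect)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(sep)[1:]
    seen_twice = sorted({h for h in header if header.count(h) > 1})
    if seen_twice:
        raise ValueError(f"{path}: duplicate sample ids {seen_twice}")
    matrix = pd.read_csv(path, sep=sep, index_col=0)
    if matrix.shape[0] == 0 or matrix.shape[1] == 0:
        raise ValueError(f"{path}: empty expression file")
    try:
        matrix = matrix.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric expression cell ({exc})") from None
    matrix.index = pd.Index([canonicalize_symbol(g) for g in matrix.index], name=matrix.index.name or "gene")
    matrix.columns = matrix.columns.astype(str)
    values = matrix.to_numpy()
    if np.isnan(values).any():
        raise ValueError(f"{path}: missing expression cells are not allowed")
    if not np.isfinite(values).all():
        raise ValueError(f"{path}: non-finite expression values")
    if (values < 0).any():
        raise ValueError(f"{path}: negative expression values")
    if not allow_duplicate_genes and matrix.index.duplicated().any():
        raise ValueError(f"{path}: duplicate gene symbols")
    return matrix


def write_expression(matrix: pd.DataFrame, path: str, dialect: str | None = None) -> None:
    matrix.to_csv(path, sep=_sep_for(path, dialect))


def collapse_duplicates(matrix: pd.DataFrame) -> pd.DataFrame:
    """Average rows sharing a gene symbol (multi-probe genes).

    Each symbol appears once in the output; its row is the arithmetic mean
    of all rows carrying that symbol. Row order follows first occurrence.
    Idempotent.
    """
    if not matrix.index.duplicated().any():
        return matrix.copy()
    order = matrix.index[~matrix.index.duplicated()]
    collapsed = matrix.groupby(level=0, sort=False).mean()
    return collapsed.loc[order]


def average_patient_samples(matrix: pd.DataFrame, sample_to_patient: Mapping[str, str]) -> pd.DataFrame:
    """Average multiple samples of one patient into a single column.

    ``sample_to_patient`` must cover every sample id in ``matrix``. Column
    order follows first occurrence of each patient. Idempotent when applied
    to its own output with an identity map.
    """
    missing = [s for s in matrix.columns if s not in sample_to_patient]
    if missing:
        raise ValueError(f"unmapped sample ids: {missing}")
    patients = pd.Index([sample_to_patient[s] for s in matrix.columns])
    order = patients[~patients.duplicated()]
    averaged = matrix.T.groupby(patients, sort=False).mean().T
    return averaged.loc[:, order]


def mad(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """Unscaled median absolute deviation: median(|x - median(x)|).

    No 1.4826 normal-consistency factor is applied; the conventional 0.5
    gene-variability threshold refers to this unscaled quantity.
    """
    values = np.asarray(values, dtype=float)
    med = np.median(values, axis=axis, keepdims=True)
    return np.median(np.abs(values - med), axis=axis)


def filter_genes(matrix: pd.DataFrame, min_mean: float = 0.0, min_mad: float = 0.5) -> pd.DataFrame:
    """Keep genes with mean expression > ``min_mean`` AND MAD > ``min_mad``.

    Values are never modified, only rows dropped. Raises if nothing
    survives, naming both thresholds.
    """
    values = matrix.to_numpy(dtype=float)
    keep = (values.mean(axis=1) > min_mean) & (mad(values, axis=1) > min_mad)
    if not keep.any():
        raise ValueError(
            f"no gene passes the filters mean > {min_mean} and MAD > {min_mad}; "
            "lower the thresholds or check the expression scale"
        )
    return matrix.loc[keep]


def restrict_to_geneset(matrix: pd.DataFrame, geneset: Iterable[str]) -> pd.DataFrame:
    """Rows restricted to the given gene set, original order preserved."""
    symbols = {canonicalize_symbol(g) for g in geneset}
    if not symbols:
        raise ValueError("empty gene set")
    keep = matrix.index.isin(symbols)
    if not keep.any():
        raise ValueError("no overlap between gene set and expression matrix")
    return matrix.loc[keep]


def read_geneset(path: str) -> set[str]:
    """Plain-text gene list, one symbol per line, '#' comments allowed."""
    symbols: set[str] = set()
    with open(path) as handle:
        for line in handle:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.add(canonicalize_symbol(line))
    if not symbols:
        raise ValueError(f"{path}: gene list is empty")
    return symbols


def read_clinical(path: str, dialect: str | None = None) -> pd.DataFrame:
    """Clinical table: mandatory sample_id, os_time (months), event columns.

    ``os_time`` must be strictly positive (cohorts exclude follow-up under
    one month upstream), ``event`` binary. Covariates may be missing per
    sample; the two mandatory columns may not.
    """
    table = pd.read_csv(path, sep=_sep_for(path, dialect))
    table = table.rename(columns={c: _CLINICAL_ALIASES.get(c.lower(), c.lower()) for c in table.columns})
    if "sample_id" not in table.columns:
        raise ValueError(f"{path}: missing mandatory column sample_id")
    table["sample_id"] = table["sample_id"].astype(str)
    if table["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    table = table.set_index("sample_id")
    for col in REQUIRED_CLINICAL:
        if col not in table.columns:
            raise ValueError(f"{path}: missing mandatory column {col}")
        if table[col].isna().any():
            raise ValueError(f"{path}: missing values in mandatory column {col}")
    table["os_time"] = table["os_time"].astype(float)
    table["event"] = table["event"].astype(int)
    if (table["os_time"] <= 0).any():
        raise ValueError(f"{path}: os_time must be strictly positive")
    if not table["event"].isin((0, 1)).all():
        raise ValueError(f"{path}: event must be 0/1")
    return table


def read_feature_table(path: str, dialect: str | None = None) -> pd.DataFrame:
    """Per-sample feature table (e.g. immune-cell fractions), samples in rows.

    Tolerates the CIBERSORTx output dialect: optional ``P-value``,
    ``Correlation`` and ``RMSE`` columns are kept (the quality p under the
    canonical name ``p_value``) and never treated as features downstream.
    """
    table = pd.read_csv(path, sep=_sep_for(path, dialect), index_col=0)
    table.index = table.index.astype(str)
    table = table.rename(columns={c: "p_value" for c in table.columns if c.lower() in ("p-value", "p_value", "pvalue")})
    if table.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return table
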