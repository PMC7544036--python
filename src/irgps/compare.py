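"""Per-feature comparison of a sample x feature table between risk groups.

Intended for externally produced immune-cell fraction tables (e.g. a
CIBERSORTx run over 22 leukocyte types): filter out low-confidence
deconvolutions by their per-sample quality p-value, then test every
feature between the high- and low-risk groups with the Wilcoxon rank-sum
test and control the false discovery rate across features by
Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["filter_quality", "compare_groups", "abundance_summary", "NON_FEATURE_COLUMNS"]

#: columns of the tolerated deconvolution-output dialect that are not features
NON_FEATURE_COLUMNS = ("p_value", "correlation", "rmse", "absolute score (sig.score)")


def _feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.lower() not in NON_FEATURE_COLUMNS]


def filter_quality(table: pd.DataFrame, p_threshold: float = 0.05) -> pd.DataFrame:
    """Drop samples whose deconvolution quality p-value is >= threshold."""
    if "p_value" not in table.columns:
        raise KeyError("quality filtering requested but the table has no p_value column")
    return table.loc[table["p_value"] < p_threshold]


def _wilcoxon(a: np.ndarray, b: np.ndarray, exact_max_n: int = 25) -> float:
    """Rank-sum p: exact when both groups are small and tie-free, else the
    normal approximation with continuity correction."""
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    tie_free = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (tie_free and max(a.size, b.size) <= exact_max_n) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def compare_groups(
    table: pd.DataFrame,
    groups: pd.Series,
    compositional: bool = False,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature two-group comparison with BH FDR across features.

    Returns a frame indexed by feature with group means/medians,
    ``wilcoxon_p``, ``t_p``, ``fdr_q`` (Benjamini-Hochberg) and a
    ``significant`` flag at ``fdr_alpha``. Features constant across both
    groups get p = 1 with a warning. With ``compositional=True`` every
    row of the feature part must sum to 1 within 1e-6.
    """
    features = _feature_columns(table)
    common = table.index.intersection(groups.dropna().index)
    data = table.loc[common, features]
    labels = groups.loc[common]
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError(f"exactly two nonempty groups required, got {uniq}")
    g1, g2 = sorted(uniq)
    if compositional:
        sums = data.to_numpy(dtype=float).sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValueError("table declared compositional but rows do not sum to 1 within 1e-6")
    a_mask = (labels == g1).to_numpy()
    rows = []
    constant_features = []
    for feat in features:
        x = data[feat].to_numpy(dtype=float)
        a, b = x[a_mask], x[~a_mask]
        if np.ptp(x) == 0:
            constant_features.append(feat)
        w_p = _wilcoxon(a, b)
        t_p = 1.0 if np.ptp(x) == 0 else float(stats.ttest_ind(a, b).pvalue)
        rows.append(
            {
                "feature": feat,
                f"mean_{g1}": a.mean(),
                f"mean_{g2}": b.mean(),
                f"median_{g1}": np.median(a),
                f"median_{g2}": np.median(b),
                "wilcoxon_p": w_p,
                "t_p": t_p,
            }
        )
    if constant_features:
        warnings.warn(f"features with identical values in every sample: {constant_features}", stacklevel=2)
    result = pd.DataFrame(rows).set_index("feature")
    reject, q, _, _ = multipletests(result["wilcoxon_p"].to_numpy(), alpha=fdr_alpha, method="fdr_bh")
    result["fdr_q"] = q
    result["significant"] = reject
    return result


def abundance_summary(table: pd.DataFrame, groups: pd.Series, min_fraction: float = 0.05) -> list[str]:
    """Features whose mean fraction exceeds ``min_fraction`` in every group."""
    if not 0 <= min_fraction <= 1:
        raise ValueError(f"min_fraction must lie in [0, 1], got {min_fraction}")
    features = _feature_columns(table)
    common = table.index.intersection(groups.dropna().index)
    data = table.loc[common, features]
    labels = groups.loc[common]
    means = data.groupby(labels).mean()
    keep = (means > min_fraction).all(axis=0) if min_fraction > 0 else pd.Series(True, index=means.columns)
    return [f for f in features if keep[f]]
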