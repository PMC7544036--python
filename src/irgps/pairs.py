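"""Within-sample gene-pair indicator features.

The pair score of an ordered pair (A, B) in a sample is 1 iff the
expression of A strictly exceeds that of B in that sample, else 0 (ties
score 0 — consequential for FPKM data, where exact zeros are common).
Scores depend only on within-sample orderings, so any strictly increasing
per-sample transformation of the expression matrix leaves them unchanged.

A PairScoreMatrix is represented as a pandas DataFrame of uint8 0/1 values
with pair ids ("GENEA__GENEB") in the index and sample ids in columns.
"""

from __future__ import annotations

import itertools
import warnings
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .signature import GenePair, Signature

__all__ = [
    "enumerate_pairs",
    "score_pairs",
    "filter_constant_pairs",
    "risk_score",
    "assign_groups",
    "pairs_of",
]


def pairs_of(psm: pd.DataFrame) -> list[GenePair]:
    """The GenePair objects indexing a pair-score matrix."""
    return [GenePair.from_id(pid) for pid in psm.index]


def enumerate_pairs(genes: Sequence[str], both_orientations: bool = False) -> list[GenePair]:
    """All ordered pairs over ``genes``.

    By default one orientation per unordered pair (n(n-1)/2 pairs); the
    reverse orientation is redundant on tie-free data by antisymmetry.
    With ``both_orientations`` all n(n-1) ordered pairs are produced.
    """
    if both_orientations:
        return [GenePair(a, b) for a, b in itertools.permutations(genes, 2)]
    return [GenePair(a, b) for a, b in itertools.combinations(genes, 2)]


def score_pairs(
    matrix: pd.DataFrame,
    pairs: Sequence[GenePair] | str = "all",
    both_orientations: bool = False,
) -> pd.DataFrame:
    """Binary pair-score matrix: 1 iff expr(gene_a) > expr(gene_b), strictly.

    ``pairs`` may be an explicit list or ``"all"`` to enumerate every pair
    of genes in ``matrix`` (one orientation each unless
    ``both_orientations``). Pairs referencing genes absent from the matrix
    are a hard error.
    """
    if isinstance(pairs, str):
        if pairs != "all":
            raise ValueError(f"pairs must be a list of GenePair or 'all', got {pairs!r}")
        pair_list = enumerate_pairs(list(matrix.index), both_orientations)
    else:
        pair_list = list(pairs)
    missing = sorted(
        {g for p in pair_list for g in (p.gene_a, p.gene_b)} - set(matrix.index)
    )
    if missing:
        raise KeyError(f"pairs reference genes absent from the expression matrix: {missing}")
    values = matrix.to_numpy(dtype=float)
    row = {g: i for i, g in enumerate(matrix.index)}
    ia = np.fromiter((row[p.gene_a] for p in pair_list), dtype=np.intp, count=len(pair_list))
    ib = np.fromiter((row[p.gene_b] for p in pair_list), dtype=np.intp, count=len(pair_list))
    scores = (values[ia] > values[ib]).astype(np.uint8)
    return pd.DataFrame(scores, index=[p.pair_id for p in pair_list], columns=matrix.columns)


def filter_constant_pairs(psm: pd.DataFrame, max_identity_fraction: float = 0.90) -> pd.DataFrame:
    """Drop near-constant pairs.

    A pair is removed iff its majority score value occupies strictly more
    than ``max_identity_fraction`` of samples; equivalently it is retained
    iff min(freq(0), freq(1)) >= 1 - max_identity_fraction. The retained
    scores are untouched.
    """
    n = psm.shape[1]
    ones = psm.to_numpy().sum(axis=1)
    majority = np.maximum(ones, n - ones) / n
    keep = majority <= max_identity_fraction
    if not keep.any():
        warnings.warn(
            f"every pair exceeds the {max_identity_fraction:.0%} identity bound; returning an empty matrix",
            stacklevel=2,
        )
    return psm.loc[keep]


def risk_score(expression_or_psm: pd.DataFrame, signature: Signature) -> pd.Series:
    """Per-sample risk score r = sum_k beta_k * s_k under a signature.

    Accepts either an expression matrix (pairs are scored on the fly) or a
    pair-score matrix containing every signature pair id. The score depends
    on expression only through pair-order indicators.
    """
    pair_ids = [p.pair_id for p in signature.pairs]
    if set(pair_ids) <= set(expression_or_psm.index):
        scores = expression_or_psm.loc[pair_ids]
    else:
        scores = score_pairs(expression_or_psm, signature.pairs)
    beta = np.asarray(signature.coefficients, dtype=float)
    values = beta @ scores.to_numpy(dtype=float)
    return pd.Series(values, index=scores.columns, name="risk_score")


def assign_groups(scores: pd.Series, cutoff: float) -> pd.Series:
    """'high' iff score > cutoff (strictly), else 'low'.

    A score exactly at the cutoff is assigned to the low-risk group.
    """
    if not np.isfinite(cutoff):
        raise ValueError(f"cutoff must be finite, got {cutoff}")
    labels = np.where(scores.to_numpy(dtype=float) > cutoff, "high", "low")
    return pd.Series(labels, index=scores.index, name="risk_group")
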