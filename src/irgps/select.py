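"""Consensus lasso-Cox selection of the final pair signature.

Penalized selection over the screened candidate pairs: many random cycles
of k-fold cross-validated L1 Cox regression, keeping the pairs whose
coefficient is nonzero at the cycle's CV-optimal penalty in at least a
given fraction of cycles. Repetition with fresh random folds stabilises
the lasso's arbitrary choices among highly correlated pairs and yields a
small, informative signature. The path fits delegate to scikit-survival's
glmnet-style coordinate-descent solver; held-out performance is the test
folds' Cox partial log-likelihood, computed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .pairs import pairs_of
from .signature import Signature

__all__ = ["select_signature", "cv_partial_loglik"]


def _breslow_partial_loglik(eta: np.ndarray, times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Breslow partial log-likelihood for each column of ``eta``.

    ``eta`` is (n_samples, n_models); ties share the full risk-set sum.
    Used only as the cross-validation criterion, where the tie correction
    is immaterial.
    """
    order = np.argsort(-times, kind="stable")  # descending: risk set = prefix
    t = times[order]
    e = events[order].astype(bool)
    eta_s = eta[order]
    # cumulative log-sum-exp down the prefix, shared across tied times
    m = eta_s.max(axis=0, keepdims=True)
    csum = np.cumsum(np.exp(eta_s - m), axis=0)
    # for a death at time t_i the risk set is everyone with t >= t_i: the
    # prefix up to the LAST index with that time
    last_idx = np.searchsorted(-t, -t, side="right") - 1
    log_risk = np.log(csum[last_idx]) + m
    return (eta_s[e] - log_risk[e]).sum(axis=0)


def cv_partial_loglik(
    X: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    alphas: np.ndarray,
    fold_ids: np.ndarray,
    l1_ratio: float = 1.0,
) -> np.ndarray:
    """Summed held-out partial log-likelihood per penalty over CV folds."""
    y = Surv.from_arrays(event=events.astype(bool), time=times)
    total = np.zeros(len(alphas))
    for fold in np.unique(fold_ids):
        test = fold_ids == fold
        train = ~test
        if events[test].sum() == 0 or events[train].sum() == 0:
            continue
        est = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas, fit_baseline_model=False)
        est.fit(X[train], y[train])
        # coef_ is (n_features, n_alphas); missing alphas (path stopped) padded below
        B = _coef_on_grid(est, alphas)
        eta_test = X[test] @ B
        total += _breslow_partial_loglik(eta_test, times[test], events[test])
    return total


def _coef_on_grid(est: CoxnetSurvivalAnalysis, alphas: np.ndarray) -> np.ndarray:
    """Coefficients aligned to the requested penalty grid.

    The solver may stop the path early; penalties it never reached reuse
    the last fitted coefficients.
    """
    fitted = np.asarray(est.alphas_)
    B = np.asarray(est.coef_)
    out = np.zeros((B.shape[0], len(alphas)))
    for j, a in enumerate(alphas):
        k = int(np.argmin(np.abs(fitted - a)))
        out[:, j] = B[:, k]
    return out


def select_signature(
    psm_candidates: pd.DataFrame,
    survival: pd.DataFrame,
    n_cycles: int = 1000,
    selection_fraction: float = 0.5,
    seed: int | None = None,
    k_folds: int = 10,
    n_alphas: int = 40,
    alpha_min_ratio: float = 0.01,
) -> Signature:
    """Consensus signature over repeated cross-validated lasso-Cox cycles.

    Parameters
    ----------
    psm_candidates : screened pair-score matrix (pairs x samples).
    survival : table with ``os_time``/``event`` covering every sample.
    n_cycles : number of random-fold CV repetitions (study default 1000).
    selection_fraction : minimum fraction of cycles in which a pair must
        be selected (nonzero at the cycle's CV-optimal penalty) to enter
        the signature.
    seed : mandatory for reproducibility; the same seed gives the same
        signature bit-for-bit.

    The final coefficients come from a single L1 fit at the median of the
    cycles' CV-optimal penalties, restricted to the kept pairs; pairs that
    are zero even there are dropped. Raises if no pair reaches the
    consensus threshold.
    """
    if seed is None:
        raise ValueError("seed is mandatory for reproducible selection")
    if psm_candidates.shape[0] == 0:
        raise ValueError("no candidate pairs supplied")
    rng = np.random.default_rng(seed)
    pairs = pairs_of(psm_candidates)
    X = psm_candidates.to_numpy(dtype=float).T  # samples x pairs
    surv = survival.loc[psm_candidates.columns]
    times = surv["os_time"].to_numpy(dtype=float)
    events = surv["event"].to_numpy(dtype=int)
    n = len(times)
    y = Surv.from_arrays(event=events.astype(bool), time=times)

    # one shared penalty grid + full-data path, reused across cycles
    full = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=alpha_min_ratio, fit_baseline_model=False
    )
    full.fit(X, y)
    alphas = np.asarray(full.alphas_)
    B_full = _coef_on_grid(full, alphas)

    selected = np.zeros(X.shape[1])
    best_alphas = np.empty(n_cycles)
    for cycle in range(n_cycles):
        fold_ids = rng.permutation(np.arange(n) % k_folds)
        ll = cv_partial_loglik(X, times, events, alphas, fold_ids)
        best = int(np.argmax(ll))
        best_alphas[cycle] = alphas[best]
        selected += B_full[:, best] != 0

    freq = selected / n_cycles
    keep = freq >= selection_fraction
    if not keep.any():
        raise ValueError(
            f"no pair selected in >= {selection_fraction:.0%} of {n_cycles} cycles; "
            "lower selection_fraction or revisit the candidate screen"
        )
    final_alpha = float(np.median(best_alphas))
    refit = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[final_alpha], fit_baseline_model=False)
    refit.fit(X[:, keep], y)
    coefs = np.asarray(refit.coef_)[:, 0]
    entries = [
        (pair, float(coef))
        for pair, keep_it, coef in zip(pairs, keep, _expand(coefs, keep))
        if keep_it and coef != 0.0
    ]
    if not entries:
        raise ValueError("all consensus pairs shrank to zero at the median CV-optimal penalty")
    note = (
        f"consensus L1 Cox over {n_cycles} random {k_folds}-fold CV cycles, "
        f"selection_fraction={selection_fraction}, penalty={final_alpha:.6g}, seed={seed}"
    )
    return Signature(entries=entries, cutoff=None, name="fitted-irgps", note=note)


def _expand(coefs_kept: np.ndarray, keep: np.ndarray) -> np.ndarray:
    """Scatter restricted-fit coefficients back onto the full pair axis."""
    out = np.zeros(keep.size)
    out[keep] = coefs_kept
    return out
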