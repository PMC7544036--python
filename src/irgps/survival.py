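"""Cohort-level survival evaluation.

Log-rank tests, Cox proportional-hazards regression (uni- and
multivariate, Efron handling of ties — appropriate for the heavy ties of
month-resolution follow-up), restricted mean survival time, risk-score
comparisons between mutation groups, and mutation-stratified subgroup
analysis. Model fitting delegates to lifelines; results are repackaged
into tidy frames mirroring the usual HR (95% CI) / p presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import restricted_mean_survival_time
from lifelines import KaplanMeierFitter
from scipy import stats

from .pairs import assign_groups

__all__ = [
    "LogRankResult",
    "CoxResult",
    "logrank_test",
    "cox_fit",
    "subgroup_analysis",
    "score_by_mutation",
    "rmst",
]


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p: float
    groups: pd.DataFrame  # per group: n, observed, expected

    def __repr__(self) -> str:  # compact, chi2-style
        return f"LogRankResult(statistic={self.statistic:.4g}, df={self.df}, p={self.p:.4g})"


@dataclass
class CoxResult:
    summary: pd.DataFrame  # per covariate: coef, hazard_ratio, ci_low, ci_high, wald_p
    n: int
    n_events: int


def _observed_expected(times: np.ndarray, events: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Per-group observed and expected event counts over the joint risk sets."""
    uniq = pd.unique(labels)
    rows = {}
    event_times = np.unique(times[events == 1])
    for g in uniq:
        mask = labels == g
        observed = float(events[mask].sum())
        expected = 0.0
        for et in event_times:
            at_risk = times >= et
            d = float(((times == et) & (events == 1)).sum())
            n_risk = float(at_risk.sum())
            expected += d * at_risk[mask].sum() / n_risk
        rows[g] = {"n": int(mask.sum()), "observed": observed, "expected": expected}
    return pd.DataFrame.from_dict(rows, orient="index")


def logrank_test(survival: pd.DataFrame, groups: pd.Series) -> LogRankResult:
    """k-sample log-rank test between the given group labels.

    ``groups`` is a per-sample label series aligned by sample id; the
    chi-square statistic has k - 1 degrees of freedom. Every group must be
    nonempty; fewer than two distinct labels is an error.
    """
    groups = groups.loc[survival.index] if set(survival.index) <= set(groups.index) else groups
    labels = np.asarray(groups)
    if pd.unique(labels).size < 2:
        raise ValueError("log-rank test needs at least two nonempty groups")
    times = survival["os_time"].to_numpy(dtype=float)
    events = survival["event"].to_numpy(dtype=int)
    res = multivariate_logrank_test(times, labels, events)
    table = _observed_expected(times, events, labels)
    return LogRankResult(
        statistic=float(res.test_statistic),
        df=int(pd.unique(labels).size - 1),
        p=float(res.p_value),
        groups=table,
    )


def cox_fit(
    survival: pd.DataFrame,
    covariates: pd.DataFrame | pd.Series | None = None,
    which: str | list[str] | None = None,
    ties: str = "efron",
) -> CoxResult:
    """Cox proportional-hazards fit on one or several covariates.

    ``which`` selects columns (a single name for a univariate fit, a list
    for multivariate); ``covariates`` may supply extra per-sample columns
    (e.g. a risk score) beyond what ``survival`` already carries. Complete
    cases only. Reports per covariate the coefficient, HR = exp(coef),
    exp(coef +/- 1.96 SE) confidence bounds and the Wald p.
    """
    frame = survival[["os_time", "event"]].copy()
    pool = survival.drop(columns=["os_time", "event"])
    if covariates is not None:
        cov = covariates.to_frame() if isinstance(covariates, pd.Series) else covariates
        pool = pool.join(cov, how="left") if not pool.empty else cov.loc[frame.index.intersection(cov.index)]
        pool = pool.loc[frame.index.intersection(pool.index)]
    if which is None:
        which = list(pool.columns)
    names = [which] if isinstance(which, str) else list(which)
    if len(names) == 0:
        raise ValueError("no covariates selected")
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate covariates requested: {names}")
    missing = [c for c in names if c not in pool.columns]
    if missing:
        raise KeyError(f"covariates not found: {missing}")
    data = frame.join(pool[names]).dropna()
    X = data[names].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(data)), X])) <= len(names):
        raise ValueError(f"collinear or constant covariates among {names}")
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(data, duration_col="os_time", event_col="event",
                       fit_options={"precision": 1e-11})
    except Exception as exc:  # lifelines ConvergenceError and friends
        raise ValueError(f"Cox fit failed for covariates {names}: {exc}") from exc
    coef = fitter.params_
    se = fitter.standard_errors_
    z = 1.959963984540054
    summary = pd.DataFrame(
        {
            "coef": coef,
            "hazard_ratio": np.exp(coef),
            "ci_low": np.exp(coef - z * se),
            "ci_high": np.exp(coef + z * se),
            "wald_p": 2.0 * stats.norm.sf(np.abs(coef / se)),
        }
    )
    summary.index.name = "variable"
    return CoxResult(summary=summary, n=len(data), n_events=int(data["event"].sum()))


def score_by_mutation(scores: pd.Series, mutation_flags: pd.Series) -> dict:
    """Compare risk scores between mutated and wild-type samples.

    Returns both the two-sample t-test and the Wilcoxon rank-sum p, with
    group means and medians. Both groups must be nonempty.
    """
    common = scores.index.intersection(mutation_flags.dropna().index)
    x = scores.loc[common].to_numpy(dtype=float)
    flag = mutation_flags.loc[common].astype(int).to_numpy()
    a, b = x[flag == 1], x[flag == 0]
    if a.size == 0 or b.size == 0:
        raise ValueError("both mutated and wild-type groups must be nonempty")
    t_p = float(stats.ttest_ind(a, b).pvalue)
    w_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return {
        "n_mut": int(a.size),
        "n_wt": int(b.size),
        "mean_mut": float(a.mean()),
        "mean_wt": float(b.mean()),
        "median_mut": float(np.median(a)),
        "median_wt": float(np.median(b)),
        "t_p": t_p,
        "wilcoxon_p": w_p,
    }


def rmst(survival: pd.DataFrame, groups: pd.Series, tau: float) -> dict:
    """Restricted mean survival time per group on [0, tau], plus a ratio.

    The RMST is the area under the group's Kaplan-Meier curve up to tau.
    With exactly two groups the ratio is high/low when the labels are
    'high'/'low', otherwise first/second in sorted label order.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    groups = groups.loc[survival.index]
    out: dict = {"tau": float(tau), "rmst": {}}
    for g in pd.unique(groups):
        sub = survival.loc[groups == g]
        kmf = KaplanMeierFitter().fit(sub["os_time"], sub["event"])
        out["rmst"][g] = float(restricted_mean_survival_time(kmf, t=tau))
    labels = sorted(out["rmst"])
    if len(labels) == 2:
        hi, lo = ("high", "low") if set(labels) == {"high", "low"} else (labels[0], labels[1])
        out["ratio"] = out["rmst"][hi] / out["rmst"][lo]
    return out


def subgroup_analysis(
    survival: pd.DataFrame,
    scores: pd.Series,
    cutoff: float,
    strata_column: str,
) -> dict:
    """Risk-group evaluation repeated within each stratum of a binary flag.

    For every value of ``strata_column`` (e.g. mutated vs wild-type):
    assign risk groups at ``cutoff``, run the log-rank test between them
    and a univariate Cox fit on the continuous score. Strata too small to
    test (one group empty, or no events) yield an NA entry with a warning
    rather than an error.
    """
    if strata_column not in survival.columns:
        raise KeyError(f"stratum column {strata_column!r} not in survival table")
    results: dict = {}
    strata = survival[strata_column]
    for value in pd.unique(strata.dropna()):
        sub = survival.loc[strata == value]
        sub_scores = scores.loc[sub.index]
        groups = assign_groups(sub_scores, cutoff)
        entry: dict = {"n": int(len(sub))}
        if pd.unique(groups).size < 2 or sub["event"].sum() == 0:
            warnings.warn(
                f"stratum {strata_column}={value}: too few groups or events; reporting NA", stacklevel=2
            )
            entry.update({"logrank": None, "cox": None})
        else:
            entry["logrank"] = logrank_test(sub[["os_time", "event"]], groups)
            try:
                entry["cox"] = cox_fit(sub[["os_time", "event"]], covariates=sub_scores.rename("risk_score"))
            except ValueError as exc:
                warnings.warn(f"stratum {strata_column}={value}: Cox fit failed ({exc}); NA", stacklevel=2)
                entry["cox"] = None
        results[value] = entry
    return results
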