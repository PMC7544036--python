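"""Time-dependent ROC at a fixed horizon under right censoring.

Cases at horizon t are subjects with an observed event by t, controls are
subjects event-free at t. Sensitivity and specificity for a marker X at
threshold c are estimated with the Kaplan-Meier ("cumulative/dynamic")
plug-in:

    sens(c) = [1 - S(t | X > c)] P(X > c) / [1 - S(t)]
    spec(c) =      S(t | X <= c) P(X <= c) /      S(t)

where S is the product-limit estimator overall or within the marker
stratum. Only order statistics of the marker enter, so the ROC is
invariant to strictly increasing marker transformations. The plug-in can
leave [0, 1] on small strata; values are clipped with a warning.

The operating cutoff is the threshold maximising sens + spec (Youden).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["KaplanMeier", "km_survival", "TimedROC", "timed_roc", "optimal_cutoff"]


@dataclass
class KaplanMeier:
    """Product-limit survival estimate S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    Right-continuous step function; S(t) = 1 before the first event.
    Calling the object evaluates it at arbitrary times.
    """

    event_times: np.ndarray
    survival: np.ndarray
    n: int
    n_events: int

    def __call__(self, t) -> np.ndarray | float:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.event_times, t_arr, side="right")
        out = np.concatenate(([1.0], self.survival))[idx]
        return out if np.ndim(t) else float(out[0])


def km_survival(times, events) -> KaplanMeier:
    """Kaplan-Meier estimate from follow-up times and event indicators."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival input")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    distinct = np.unique(t[e == 1])
    n_at_risk = t.size - np.searchsorted(t, distinct, side="left")
    d = np.array([np.sum((t == et) & (e == 1)) for et in distinct], dtype=float)
    surv = np.cumprod(1.0 - d / n_at_risk)
    return KaplanMeier(event_times=distinct, survival=surv, n=t.size, n_events=int(e.sum()))


@dataclass
class TimedROC:
    """ROC at a fixed horizon: thresholds are the observed marker values."""

    horizon: float
    thresholds: np.ndarray
    sens: np.ndarray
    spec: np.ndarray
    auc: float

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "sens": self.sens, "spec": self.spec})


def timed_roc(scores, survival: pd.DataFrame, horizon: float = 36.0) -> TimedROC:
    """Cumulative/dynamic time-dependent ROC of a marker at ``horizon``.

    ``scores`` is a per-sample marker (pd.Series indexed by sample id or
    array aligned to ``survival``); ``survival`` needs ``os_time`` and
    ``event`` columns. The horizon must lie after the first event and
    within the follow-up range.
    """
    if isinstance(scores, pd.Series):
        surv = survival.loc[scores.index]
        x = scores.to_numpy(dtype=float)
    else:
        surv = survival
        x = np.asarray(scores, dtype=float)
    times = surv["os_time"].to_numpy(dtype=float)
    events = surv["event"].to_numpy(dtype=int)
    if horizon > times.max():
        raise ValueError(f"horizon {horizon} beyond the observed follow-up range (max {times.max()})")
    event_times = times[events == 1]
    if event_times.size == 0 or horizon < event_times.min():
        raise ValueError(f"horizon {horizon} precedes the first observed event")

    km_all = km_survival(times, events)
    s_all = km_all(horizon)
    if s_all >= 1.0 or s_all <= 0.0:
        raise ValueError(f"overall survival at horizon is {s_all}; ROC undefined")

    thresholds = np.unique(x)
    n = x.size
    sens = np.empty(thresholds.size)
    spec = np.empty(thresholds.size)
    for i, c in enumerate(thresholds):
        above = x > c
        p_above = above.mean()
        s_above = km_survival(times[above], events[above])(horizon) if above.any() else 1.0
        s_below = km_survival(times[~above], events[~above])(horizon) if (~above).any() else 1.0
        sens[i] = (1.0 - s_above) * p_above / (1.0 - s_all)
        spec[i] = s_below * (1.0 - p_above) / s_all
    if (sens < -1e-12).any() or (sens > 1 + 1e-12).any() or (spec < -1e-12).any() or (spec > 1 + 1e-12).any():
        if (sens < -0.01).any() or (sens > 1.01).any() or (spec < -0.01).any() or (spec > 1.01).any():
            warnings.warn("KM plug-in sensitivity/specificity left [0, 1]; clipping", stacklevel=2)
    sens = np.clip(sens, 0.0, 1.0)
    spec = np.clip(spec, 0.0, 1.0)

    # AUC by trapezoid along the threshold-ordered (FPR, TPR) path from its
    # (1,1) limit down to (0,0); integrating in path order (not sorted) keeps
    # nominally-vertical staircase segments vertical despite float jitter
    fpr = np.concatenate(([1.0], 1.0 - spec, [0.0]))
    tpr = np.concatenate(([1.0], sens, [0.0]))
    auc = float(-np.sum(np.diff(fpr) * (tpr[1:] + tpr[:-1]) / 2.0))
    return TimedROC(horizon=float(horizon), thresholds=thresholds, sens=sens, spec=spec, auc=auc)


def optimal_cutoff(roc: TimedROC) -> tuple[float, float, float]:
    """Threshold maximising sens + spec; ties go to the smaller threshold.

    Returns ``(cutoff, sens, spec)`` at the optimum.
    """
    if roc.thresholds.size == 0:
        raise ValueError("empty ROC")
    youden = roc.sens + roc.spec
    best = int(np.argmax(youden))  # argmax takes the first of ties; thresholds ascend
    return float(roc.thresholds[best]), float(roc.sens[best]), float(roc.spec[best])
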