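"""Kaplan-Meier estimation and the G-group log-rank test."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SurvivalCurve", "kaplan_meier", "logrank_test"]


@dataclass
class SurvivalCurve:
    """Product-limit estimate of a survival function.

    ``event_times`` are the distinct times with at least one event,
    ascending; ``survival`` the estimate just after each of them; ``at_risk``
    and ``n_events`` the risk-set size and event count at each.  Subjects
    censored at an event time remain at risk at that time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t):
        """Right-continuous step-function evaluation S(t)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.event_times, t, side="right")
        vals = np.concatenate([[1.0], self.survival])
        return vals[idx]

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5; inf if never reached."""
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.event_times[below[0]]) if below.size else float("inf")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "at_risk": self.at_risk,
                "events": self.n_events,
                "survival": self.survival,
            }
        )


def kaplan_meier(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    ``S(t) = prod_{t_k <= t} (1 - d_k / n_k)`` over distinct event times t_k
    with d_k events and n_k subjects at risk (time >= t_k).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if times.size == 0:
        raise ValueError("empty input")
    if np.any(times <= 0):
        raise ValueError("times must be strictly positive")

    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order].astype(bool)
    distinct, first_idx, inverse = np.unique(t, return_index=True, return_inverse=True)
    n = len(t)
    d_k = np.bincount(inverse, weights=e.astype(float), minlength=len(distinct))
    n_k = n - first_idx  # sorted: subjects with time >= tk

    has_event = d_k > 0
    surv = np.cumprod(1.0 - d_k[has_event] / n_k[has_event])
    return SurvivalCurve(
        event_times=distinct[has_event],
        survival=surv,
        at_risk=n_k[has_event].astype(int),
        n_events=d_k[has_event].astype(int),
        censor_times=np.sort(times[events == 0]),
    )


def logrank_test(times, events, groups):
    """G-group log-rank test.

    At each distinct event time the observed events per group are compared
    with their expectation under a common hazard; the covariance of the
    (O - E) vector accumulates the multivariate hypergeometric terms.  The
    statistic uses the first G-1 groups and a pseudo-inverse for safety.

    Returns ``(chi2, df, p)`` with ``df = G - 1``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    G = len(labels)
    if G < 2:
        raise ValueError("log-rank test requires at least 2 groups")
    gidx = np.searchsorted(labels, groups)

    event_times = np.unique(times[events == 1])
    o_minus_e = np.zeros(G)
    V = np.zeros((G, G))
    for tk in event_times:
        at_risk = times >= tk
        n = at_risk.sum()
        d = float(((times == tk) & (events == 1)).sum())
        n_g = np.bincount(gidx[at_risk], minlength=G).astype(float)
        d_g = np.bincount(gidx[(times == tk) & (events == 1)], minlength=G).astype(float)
        e_g = d * n_g / n
        o_minus_e += d_g - e_g
        if n > 1:
            factor = d * (n - d) / (n - 1.0)
            V += factor * (np.diag(n_g * n) - np.outer(n_g, n_g)) / n**2

    u = o_minus_e[:-1]
    Vr = V[:-1, :-1]
    chi2 = float(u @ np.linalg.pinv(Vr) @ u) if Vr.size else 0.0
    chi2 = max(chi2, 0.0)
    df = G - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))
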