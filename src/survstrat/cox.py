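"""Cox proportional-hazards estimation by partial likelihood.

Implements Newton-Raphson maximisation of the Cox partial likelihood with
Efron (default) or Breslow handling of tied event times, bidirectional
stepwise model selection by AIC, Schoenfeld residuals, and the
Grambsch-Therneau score test of the proportional-hazards assumption.

Design matrices are built from a cohort DataFrame: numeric columns enter
as-is, categorical (non-numeric) columns are reference-coded against the
first level in sorted order, and ``a:b`` interaction terms multiply the
expanded columns of ``a`` with those of ``b``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats
from sklearn.base import BaseEstimator

__all__ = [
    "CoxFit",
    "ModelScope",
    "PHTestResult",
    "CoxPH",
    "fit_cox",
    "stepwise_aic",
    "linear_predictor",
    "schoenfeld_residuals",
    "test_ph",
]


# ---------------------------------------------------------------------------
# design matrix construction
# ---------------------------------------------------------------------------

def _is_categorical(s: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(s)


def _term_columns(cohort: pd.DataFrame, term: str, levels: dict) -> dict:
    """Expand one term into named numeric columns.

    ``levels`` caches categorical levels (first sorted level = reference) so
    a fit's coding can be replayed on new data.
    """
    if ":" in term:
        a, b = term.split(":", 1)
        ca = _term_columns(cohort, a, levels)
        cb = _term_columns(cohort, b, levels)
        out = {}
        for na, va in ca.items():
            for nb, vb in cb.items():
                out[f"{na}:{nb}"] = va * vb
        return out
    if term not in cohort.columns:
        raise KeyError(f"cohort is missing the column '{term}'")
    col = cohort[term]
    if _is_categorical(col):
        if term not in levels:
            levels[term] = tuple(sorted(map(str, pd.unique(col.astype(str)))))
        lv = levels[term]
        vals = col.astype(str)
        unknown = set(vals) - set(lv)
        if unknown:
            raise ValueError(f"column '{term}' has unseen categories: {sorted(unknown)}")
        # reference coding: drop the first sorted level
        return {f"{term}[{l}]": (vals == l).to_numpy(float) for l in lv[1:]}
    return {term: col.to_numpy(float)}


def build_design(cohort: pd.DataFrame, terms, levels: dict | None = None):
    """Build the numeric design matrix for ``terms``.

    Returns ``(X, column_names, column_term, levels)`` where ``column_term``
    maps each expanded column back to its source term.  Constant columns are
    dropped (they carry no partial-likelihood information); a rank-deficient
    design raises naming the collinear columns.
    """
    levels = {} if levels is None else dict(levels)
    cols, names, col_term = [], [], []
    for term in terms:
        for cname, cvals in _term_columns(cohort, term, levels).items():
            cols.append(np.asarray(cvals, dtype=float))
            names.append(cname)
            col_term.append(term)
    if cols:
        X = np.column_stack(cols)
        keep = X.std(axis=0) > 0
        X = X[:, keep]
        names = [n for n, k in zip(names, keep) if k]
        col_term = [t for t, k in zip(col_term, keep) if k]
    else:
        X = np.empty((len(cohort), 0))
    if X.shape[1]:
        _, r, piv = linalg.qr(X - X.mean(axis=0), mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
        rank = int((diag > tol).sum())
        if rank < X.shape[1]:
            bad = sorted(names[j] for j in piv[rank:])
            raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return X, names, col_term, levels


# ---------------------------------------------------------------------------
# partial likelihood
# ---------------------------------------------------------------------------

class _PLData:
    """Pre-sorted arrays for repeated partial-likelihood evaluation."""

    def __init__(self, X, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        order = np.argsort(-time, kind="stable")  # descending time
        self.X = np.asarray(X, dtype=float)[order]
        self.time = time[order]
        self.event = event[order].astype(bool)
        self.n, self.p = self.X.shape
        # groups of tied times, in descending time order
        boundaries = np.flatnonzero(np.diff(self.time) != 0) + 1
        self.groups = np.split(np.arange(self.n), boundaries)
        self.n_events = int(self.event.sum())


def _loglik_grad_hess(data: _PLData, beta, ties="efron"):
    """Log partial likelihood, gradient and Hessian at ``beta``.

    Iterates over tied-time groups in descending time order, accumulating
    the risk-set sums S0 = sum w, S1 = sum w x, S2 = sum w x x'.  For a group
    with d tied events, Efron's correction subtracts the fraction l/d of the
    tied contribution from each of the d denominator terms; Breslow uses the
    full risk set for all d.
    """
    X, ev = data.X, data.event
    p = data.p
    eta = X @ beta
    eta_c = eta - eta.max()  # overflow guard; constants cancel in the PL
    w = np.exp(eta_c)
    wx = w[:, None] * X

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    for g in data.groups:
        S0 += w[g].sum()
        S1 += wx[g].sum(axis=0)
        S2 += np.einsum("i,ij,ik->jk", w[g], X[g], X[g])
        eidx = g[ev[g]]
        d = len(eidx)
        if d == 0:
            continue
        loglik += eta_c[eidx].sum()
        grad += X[eidx].sum(axis=0)
        efron = ties == "efron" and d > 1
        if efron:
            t0 = w[eidx].sum()
            t1 = wx[eidx].sum(axis=0)
            t2 = np.einsum("i,ij,ik->jk", w[eidx], X[eidx], X[eidx])
        for l in range(d):
            if efron:
                frac = l / d
                phi0 = S0 - frac * t0
                phi1 = S1 - frac * t1
                phi2 = S2 - frac * t2
            else:
                phi0, phi1, phi2 = S0, S1, S2
            loglik -= np.log(phi0)
            psi = phi1 / phi0
            grad -= psi
            hess -= phi2 / phi0 - np.outer(psi, psi)
    # the eta shift cancels exactly: each event adds -max(eta) in the
    # numerator and each of the d log-denominators absorbs it once
    return loglik, grad, hess


def _maximize_partial_likelihood(data: _PLData, ties, tol=1e-8, max_iter=50):
    beta = np.zeros(data.p)
    loglik, grad, hess = _loglik_grad_hess(data, beta, ties)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        new_beta = beta + step
        new_ll, new_grad, new_hess = _loglik_grad_hess(data, new_beta, ties)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < loglik - 1e-12) and halvings < 25:
            step *= 0.5
            new_beta = beta + step
            new_ll, new_grad, new_hess = _loglik_grad_hess(data, new_beta, ties)
            halvings += 1
        beta, loglik, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(beta)) > 500:  # monotone likelihood
            break
    else:
        n_iter = max_iter
    if not converged and np.max(np.abs(grad)) < tol:
        converged = True
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-hess)
    return beta, cov, loglik, converged, n_iter


# ---------------------------------------------------------------------------
# public types
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    """A fitted proportional-hazards model.

    ``terms`` are the model terms as requested; ``columns`` the expanded
    design columns carrying one coefficient each.  ``aic`` satisfies
    ``-2 * log_partial_likelihood + 2 * len(beta)``.
    """

    terms: tuple
    columns: tuple
    column_term: tuple
    beta: np.ndarray
    covariance: np.ndarray
    log_partial_likelihood: float
    aic: float
    n_events: int
    ties_method: str
    converged: bool
    n_iter: int
    levels: dict = field(default_factory=dict)
    time_col: str = "time"
    event_col: str = "event"

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    @property
    def p_values(self) -> np.ndarray:
        se = self.se
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, self.beta / se, np.inf)
        return 2.0 * stats.norm.sf(np.abs(z))

    def to_dict(self) -> dict:
        return {
            "terms": list(self.terms),
            "columns": list(self.columns),
            "beta": [float(b) for b in self.beta],
            "se": [float(s) for s in self.se],
            "p": [float(p) for p in self.p_values],
            "log_partial_likelihood": float(self.log_partial_likelihood),
            "aic": float(self.aic),
            "n_events": self.n_events,
            "ties_method": self.ties_method,
            "converged": self.converged,
        }


@dataclass
class ModelScope:
    """Search scope for one biomarker's stepwise Cox model.

    ``forced_terms`` (default: the biomarker main effect) are never dropped;
    interactions pair the scope's biomarker with one of its confounders.
    """

    biomarker: str
    confounders: tuple = ()
    interactions: tuple = ()
    forced_terms: tuple | None = None

    def __post_init__(self):
        self.confounders = tuple(self.confounders)
        self.interactions = tuple(
            tuple(p.split(":", 1)) if isinstance(p, str) else tuple(p)
            for p in self.interactions
        )
        if self.forced_terms is None:
            self.forced_terms = (self.biomarker,)
        self.forced_terms = tuple(self.forced_terms)
        for a, b in self.interactions:
            if a != self.biomarker or b not in self.confounders:
                raise ValueError(
                    f"interaction ({a}, {b}) must pair the scope biomarker "
                    f"'{self.biomarker}' with one of its confounders"
                )

    @property
    def interaction_terms(self) -> tuple:
        return tuple(f"{a}:{b}" for a, b in self.interactions)

    @property
    def full_terms(self) -> tuple:
        return (self.biomarker,) + self.confounders + self.interaction_terms


@dataclass
class PHTestResult:
    """Grambsch-Therneau proportional-hazards test result."""

    columns: tuple
    statistics: np.ndarray  # per-column chi-square, 1 df each
    p_values: np.ndarray
    global_statistic: float
    global_p: float
    df: int
    time_transform: str


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class CoxPH(BaseEstimator):
    """Cox proportional-hazards regression on a numeric design matrix.

    Parameters
    ----------
    ties : {'efron', 'breslow'}
        Correction for tied event times.
    tol : float
        Newton-Raphson stops when the gradient infinity-norm drops below
        this value.
    max_iter : int
        Maximum Newton-Raphson iterations.

    Attributes (after ``fit``)
    --------------------------
    coef_ : (p,) log hazard ratios maximising the partial likelihood.
    covariance_ : (p, p) inverse observed information.
    log_likelihood_ : log partial likelihood at the optimum.
    aic_ : ``-2 * log_likelihood_ + 2 * p``.
    n_events_ : number of observed events.
    converged_ : whether the gradient tolerance was reached.
    """

    def __init__(self, ties: str = "efron", tol: float = 1e-8, max_iter: int = 50):
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        """Fit to design ``X`` and survival outcome ``y = (time, event)``.

        ``y`` is an (n, 2) array-like whose first column is the follow-up
        time and second the event indicator.
        """
        if self.ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        y = np.asarray(y, dtype=float)
        time, event = y[:, 0], y[:, 1]
        if np.any(time <= 0):
            raise ValueError("times must be strictly positive")
        if not set(np.unique(event)) <= {0.0, 1.0}:
            raise ValueError("event indicators must be 0 or 1")
        if event.sum() < 1:
            raise ValueError("at least one event is required")
        data = _PLData(X, time, event)
        beta, cov, loglik, converged, n_iter = _maximize_partial_likelihood(
            data, self.ties, tol=self.tol, max_iter=self.max_iter
        )
        self.coef_ = beta
        self.covariance_ = cov
        self.log_likelihood_ = float(loglik)
        self.aic_ = -2.0 * self.log_likelihood_ + 2.0 * X.shape[1]
        self.n_events_ = data.n_events
        self.converged_ = bool(converged)
        self.n_iter_ = n_iter
        return self

    def predict(self, X):
        """Linear predictor ``X @ coef_`` (uncentred)."""
        return np.asarray(X, dtype=float) @ self.coef_


# ---------------------------------------------------------------------------
# cohort-level operations
# ---------------------------------------------------------------------------

def _prepare(cohort, terms, time_col, event_col, levels=None):
    X, names, col_term, levels = build_design(cohort, terms, levels)
    time = cohort[time_col].to_numpy(float)
    event = cohort[event_col].to_numpy(float)
    return X, names, col_term, levels, time, event


def terms_columns(terms):
    cols = []
    for t in terms:
        cols.extend(t.split(":") if ":" in t else [t])
    return sorted(set(cols))


def fit_cox(cohort: pd.DataFrame, terms, ties: str = "efron",
            time_col: str = "time", event_col: str = "event") -> CoxFit:
    """Fit a Cox model for ``terms`` on a cohort table.

    Rows with missing values in any referenced column are dropped
    (complete-case analysis per model); more than 20% dropped is an error.
    """
    terms = tuple(terms)
    needed = terms_columns(terms) + [time_col, event_col]
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise KeyError(f"cohort is missing columns: {missing_cols}")
    sub = cohort.dropna(subset=needed)
    if len(sub) < len(cohort):
        dropped = len(cohort) - len(sub)
        if dropped > 0.2 * len(cohort):
            raise ValueError(
                f"complete-case filtering would drop {dropped}/{len(cohort)} patients"
            )
        warnings.warn(f"dropped {dropped} patients with missing values")
    X, names, col_term, levels, time, event = _prepare(sub, terms, time_col, event_col)
    est = CoxPH(ties=ties).fit(X, np.column_stack([time, event]))
    return CoxFit(
        terms=terms,
        columns=tuple(names),
        column_term=tuple(col_term),
        beta=est.coef_,
        covariance=est.covariance_,
        log_partial_likelihood=est.log_likelihood_,
        aic=est.aic_,
        n_events=est.n_events_,
        ties_method=ties,
        converged=est.converged_,
        n_iter=est.n_iter_,
        levels=levels,
        time_col=time_col,
        event_col=event_col,
    )


def linear_predictor(fit: CoxFit, cohort: pd.DataFrame) -> np.ndarray:
    """Per-patient risk score eta = x . beta, centred to cohort mean zero."""
    X, names, _, _ = build_design(cohort, fit.terms, fit.levels)
    if tuple(names) != tuple(fit.columns):
        # new data may lack variation in a column that was constant at fit
        # time or vice versa; rebuild without the constant-column drop
        X = _design_like(cohort, fit)
    eta = X @ fit.beta
    return eta - eta.mean()


def _design_like(cohort, fit: CoxFit):
    cols = []
    levels = dict(fit.levels)
    expanded = {}
    for term in fit.terms:
        expanded.update(_term_columns(cohort, term, levels))
    try:
        return np.column_stack([np.asarray(expanded[c], float) for c in fit.columns])
    except KeyError as exc:
        raise KeyError(f"cohort is missing the design column {exc}") from exc


def stepwise_aic(cohort: pd.DataFrame, scope: ModelScope, ties: str = "efron",
                 time_col: str = "time", event_col: str = "event") -> CoxFit:
    """Bidirectional stepwise Cox model selection by AIC.

    Starts from the full scope model; at each step the single add or drop
    move giving the largest AIC decrease is taken, stopping at a local
    minimum.  Forced terms are never dropped, and model hierarchy is
    respected: an interaction may only be present together with both of its
    main effects (the biomarker main effect is forced by default).
    """
    full = scope.full_terms
    current = fit_cox(cohort, full, ties=ties, time_col=time_col, event_col=event_col)
    cache = {full: current}

    def fit_terms(terms):
        terms = tuple(terms)
        if terms not in cache:
            try:
                cache[terms] = fit_cox(cohort, terms, ties=ties,
                                       time_col=time_col, event_col=event_col)
            except (ValueError, np.linalg.LinAlgError):
                cache[terms] = None
        return cache[terms]

    while True:
        terms = set(current.terms)
        moves = []
        for t in current.terms:  # drops
            if t in scope.forced_terms:
                continue
            if ":" not in t and any(
                ":" in it and t in it.split(":") for it in terms if it != t
            ):
                continue  # main effect shielded by an active interaction
            moves.append(tuple(x for x in current.terms if x != t))
        for t in scope.full_terms:  # adds
            if t in terms:
                continue
            if ":" in t:
                a, b = t.split(":", 1)
                if a not in terms or b not in terms:
                    continue
            moves.append(current.terms + (t,))
        best = current
        for cand in moves:
            f = fit_terms(cand)
            if f is not None and f.converged and f.aic < best.aic - 1e-10:
                best = f
        if best is current:
            return current
        current = best


# ---------------------------------------------------------------------------
# Schoenfeld residuals and the proportional-hazards test
# ---------------------------------------------------------------------------

def schoenfeld_residuals(fit: CoxFit, cohort: pd.DataFrame):
    """Schoenfeld residuals at each observed event.

    For the event of patient i at time t_i, the residual is
    ``x_i - xbar(beta, t_i)`` with ``xbar`` the exp(eta)-weighted mean of the
    covariates over the risk set {j : t_j >= t_i}.  Returns
    ``(event_times, residuals)`` in ascending event-time order.
    """
    sub = cohort.dropna(subset=terms_columns(list(fit.terms)) + [fit.time_col, fit.event_col])
    X = _design_like(sub, fit)
    time = sub[fit.time_col].to_numpy(float)
    event = sub[fit.event_col].to_numpy(float).astype(bool)
    if event.sum() < 1:
        raise ValueError("no events")
    w = np.exp(X @ fit.beta - (X @ fit.beta).max())
    order = np.argsort(time, kind="stable")
    X, time, event, w = X[order], time[order], event[order], w[order]
    n = len(time)

    ev_idx = np.flatnonzero(event)
    resid = np.empty((len(ev_idx), X.shape[1]))
    for k, i in enumerate(ev_idx):
        at_risk = time >= time[i]
        ww = w[at_risk]
        xbar = (ww[:, None] * X[at_risk]).sum(axis=0) / ww.sum()
        resid[k] = X[i] - xbar
    return time[ev_idx], resid


def test_ph(fit: CoxFit, cohort: pd.DataFrame, transform: str = "km") -> PHTestResult:
    """Grambsch-Therneau score test of proportional hazards.

    Regresses the (scaled) Schoenfeld residuals on a transform g(t) of event
    time and tests for zero slope; a time-varying coefficient shows up as a
    trend.  With d events, u = sum_k (g_k - gbar) s_k and the observed
    information I from the fit, the global statistic is
    ``d * u' I^{-1} u / sum_k (g_k - gbar)^2`` on p degrees of freedom, and
    the per-column statistic ``d * (I^{-1} u)_j^2 / ((I^{-1})_jj * sum c^2)``
    on 1 df.

    transform: 'km' uses 1 - KM(t) from the same data, 'rank' the event-time
    ranks, 'identity' raw time.
    """
    if not fit.converged:
        raise ValueError("PH test requires a converged fit")
    etimes, resid = schoenfeld_residuals(fit, cohort)
    d = len(etimes)
    if d < 2:
        raise ValueError("PH test requires at least 2 events")
    if transform == "km":
        from .survival import kaplan_meier

        sub = cohort.dropna(subset=terms_columns(list(fit.terms)) + [fit.time_col, fit.event_col])
        curve = kaplan_meier(sub[fit.time_col].to_numpy(float),
                             sub[fit.event_col].to_numpy(float))
        g = 1.0 - curve.survival_at(etimes)
    elif transform == "rank":
        g = stats.rankdata(etimes)
    elif transform == "identity":
        g = etimes.astype(float)
    else:
        raise ValueError("transform must be 'km', 'identity' or 'rank'")

    c = g - g.mean()
    denom = float((c ** 2).sum())
    if denom <= 0:
        raise ValueError("degenerate time transform (all event times equal)")
    u = resid.T @ c
    cov = fit.covariance
    covu = cov @ u
    global_stat = float(d * u @ covu / denom)
    p = len(u)
    per = d * covu ** 2 / (np.clip(np.diag(cov), 1e-300, None) * denom)
    return PHTestResult(
        columns=fit.columns,
        statistics=per,
        p_values=stats.chi2.sf(per, 1),
        global_statistic=global_stat,
        global_p=float(stats.chi2.sf(global_stat, p)),
        df=p,
        time_transform=transform,
    )
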