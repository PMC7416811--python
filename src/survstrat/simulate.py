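"""Synthetic cohort generation.

Emulates a palliative liver-malignancy cohort with latent prognostic
subgroups: subgroup-shifted biomarker distributions, proportional-hazards
survival times from a Weibull baseline (so the PH assumption holds by
construction), and right censoring from an exponential dropout process
calibrated to a target censored fraction plus administrative censoring.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    COMET_CLASSES,
    CONFOUNDER_LEVELS,
    CONFOUNDER_RISK_LEVEL,
    SimulationConfig,
)

__all__ = ["generate_cohort", "generate_survival_times"]


def generate_survival_times(linear_predictors, config: SimulationConfig, rng=None):
    """Draw (time, event) from a Weibull-baseline Cox model.

    The latent event time is obtained by inverse-transform sampling,
    ``T = scale * (-log(U) / exp(lp)) ** (1/shape)``, which satisfies
    proportional hazards exactly.  An independent exponential censoring time
    is drawn with its rate calibrated by bisection so the expected censored
    fraction (including administrative censoring at ``admin_censor_time``)
    matches ``config.censoring_rate``.

    Returns ``(times, events)`` with ``events[i] = 1`` when the latent event
    time was observed.
    """
    lp = np.asarray(linear_predictors, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear_predictors must be finite")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    u = rng.uniform(size=lp.shape)
    latent = config.baseline_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / config.baseline_shape)

    admin = config.admin_censor_time
    rate = _calibrate_censoring_rate(latent, config.censoring_rate, admin)
    if rate > 0:
        dropout = rng.exponential(1.0 / rate, size=lp.shape)
    else:
        dropout = np.full(lp.shape, np.inf)

    censor = np.minimum(dropout, admin)
    times = np.minimum(latent, censor)
    events = (latent <= censor).astype(int)
    # guard against exact zeros from underflow; times must stay positive
    times = np.maximum(times, np.finfo(float).tiny)
    return times, events


def _calibrate_censoring_rate(latent, target, admin):
    """Bisection for the exponential dropout rate hitting ``target``.

    Expected censored fraction given the realised latent times T_i:
    ``f(rate) = 1 - mean(1[T_i <= admin] * exp(-rate * T_i))``, which is
    monotone increasing in the rate.  When administrative censoring alone
    already exceeds the target, the dropout process is switched off.
    """
    if target <= 0:
        return 0.0
    finite = np.asarray(latent, dtype=float)
    observed = finite <= admin
    floor = 1.0 - observed.mean()  # censored fraction with rate 0
    if target <= floor:
        return 0.0

    def frac(rate):
        return 1.0 - float(np.mean(observed * np.exp(-rate * finite)))

    lo, hi = 0.0, 1.0
    while frac(hi) < target and hi < 1e8:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a seeded synthetic cohort table.

    One row per patient: ``patient_id``, survival ``time`` (months) and
    ``event`` indicator, confounders (age, gender, therapy, diagnosis,
    comorbidities), one column per biomarker, and the latent
    ``true_subgroup`` label.  Identical config (including seed) yields a
    bit-identical table.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    names = list(config.biomarker_names)
    means = np.asarray(config.subgroup_biomarker_means, dtype=float)

    subgroup = rng.integers(0, config.n_subgroups, size=n)

    # biomarkers: comet classes jointly Dirichlet, the rest Gaussian
    comet_idx = config.comet_indices()
    values = np.empty((n, len(names)))
    gauss_idx = [j for j in range(len(names)) if j not in comet_idx]
    if gauss_idx:
        noise = rng.normal(0.0, config.biomarker_noise_sd, size=(n, len(gauss_idx)))
        values[:, gauss_idx] = means[np.ix_(subgroup, gauss_idx)] + noise
    if comet_idx:
        alphas = means[:, comet_idx] * config.comet_concentration
        draws = np.empty((n, len(comet_idx)))
        for i in range(n):  # per-patient draw keeps the stream order stable
            draws[i] = rng.dirichlet(alphas[subgroup[i]])
        values[:, comet_idx] = draws

    confounders = _draw_confounders(rng, n, subgroup, config)

    lp = values @ np.array([config.hazard_coefficients.get(b, 0.0) for b in names])
    lp = lp + _confounder_lp(confounders, config)
    lp = lp - lp.mean()  # baseline absorbs the location
    times, events = generate_survival_times(lp, config, rng=rng)

    table = pd.DataFrame({"patient_id": [f"P{i + 1:04d}" for i in range(n)]})
    table["time"] = times
    table["event"] = events
    for key, col in confounders.items():
        table[key] = col
    for j, name in enumerate(names):
        table[name] = values[:, j]
    table["true_subgroup"] = subgroup
    return table


def _draw_confounders(rng, n, subgroup, config):
    out = {"age": np.clip(rng.normal(65.0, 10.0, size=n), 30.0, 90.0)}
    for name, (levels, probs) in CONFOUNDER_LEVELS.items():
        probs = np.asarray(probs, dtype=float)
        if config.confounded_mode and name == "therapy":
            # optional robustness mode: therapy allocation depends on subgroup
            p_tace = np.clip(0.25 + 0.2 * subgroup, 0.05, 0.95)
            draws = rng.uniform(size=n)
            out[name] = np.where(draws < p_tace, "TACE", "SIRT")
        else:
            out[name] = rng.choice(levels, size=n, p=probs / probs.sum())
    return out


def _confounder_lp(confounders, config):
    """Confounder contribution to the log hazard.

    ``age`` enters linearly (centred at 65); a categorical confounder's
    coefficient multiplies the indicator of its designated risk level
    (male, TACE, HCC, multiple comorbidities).
    """
    lp = np.zeros(len(confounders["age"]))
    for name, coef in config.confounder_coefficients.items():
        if coef == 0.0:
            continue
        if name == "age":
            lp = lp + coef * (confounders["age"] - 65.0)
        else:
            risk = CONFOUNDER_RISK_LEVEL[name]
            lp = lp + coef * (np.asarray(confounders[name]) == risk)
    return lp
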