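"""Cox partial-likelihood engine: brute-force oracles, stepwise AIC, PH test."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

import survstrat as ss
from survstrat.cox import ModelScope, _loglik_grad_hess, _PLData

from conftest import random_survival_cohort


def exact_partial_likelihood_1d(beta, time, event, x):
    """Independent oracle: log partial likelihood for one covariate, no ties."""
    ll = 0.0
    for i in np.flatnonzero(event):
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def brute_force_beta(time, event, x):
    """Golden-section maximisation of the exact 1-covariate partial likelihood."""
    res = minimize_scalar(
        lambda b: -exact_partial_likelihood_1d(b, time, event, x),
        bounds=(-12, 12), method="bounded", options={"xatol": 1e-10},
    )
    return res.x


def small_datasets(max_n=8, seeds_per_n=10):
    """Deterministic family of 1-covariate datasets with <= max_n patients,
    distinct times, at least one event, excluding separated configurations
    (monotone likelihood has no interior maximum to compare against)."""
    out = []
    for n in range(2, max_n + 1):
        for seed in range(seeds_per_n):
            rng = np.random.default_rng(1000 * n + seed)
            time = rng.permutation(np.arange(1.0, n + 1.0))
            event = rng.binomial(1, 0.8, size=n)
            if event.sum() == 0:
                event[rng.integers(n)] = 1
            x = rng.normal(size=n) if seed % 2 else rng.binomial(1, 0.5, n).astype(float)
            if np.ptp(x) == 0:
                continue
            grid_ll = [exact_partial_likelihood_1d(b, time, event, x)
                       for b in (-2.0, 0.0, 2.0)]
            if np.ptp(grid_ll) < 1e-10:
                continue  # flat likelihood (no risk set carries information)
            beta_star = brute_force_beta(time, event, x)
            if abs(beta_star) > 8:  # effectively separated; skip
                continue
            out.append((time, event, x, beta_star))
    return out


class TestFitCox:
    def test_toy_matches_closed_form_partial_likelihood(self, toy_cohort):
        # L(b) = [e^b/(2e^b+2)] * [1/(e^b+2)] * [e^b/(e^b+1)]
        def negpl(b):
            eb = np.exp(b)
            return -(np.log(eb / (2 * eb + 2)) + np.log(1 / (eb + 2))
                     + np.log(eb / (eb + 1)))

        oracle = minimize_scalar(negpl, bounds=(-10, 10), method="bounded",
                                 options={"xatol": 1e-10}).x
        fit = ss.fit_cox(toy_cohort, ["x"])
        assert fit.converged
        assert abs(fit.beta[0] - oracle) < 1e-6

    def test_brute_force_equivalence_small_datasets(self):
        datasets = small_datasets()
        assert len(datasets) >= 30
        for time, event, x, beta_star in datasets:
            df = pd.DataFrame({"time": time, "event": event, "x": x,
                               "patient_id": np.arange(len(time))})
            fit = ss.fit_cox(df, ["x"])
            assert fit.converged
            assert abs(fit.beta[0] - beta_star) < 1e-6

    def test_null_log_likelihood_closed_form(self):
        # at beta=0 with no ties: -sum over events of log(risk-set size)
        df = random_survival_cohort(seed=3, n=40)
        data = _PLData(df[["x1", "x2"]].to_numpy(), df["time"].to_numpy(),
                       df["event"].to_numpy())
        ll0 = _loglik_grad_hess(data, np.zeros(2))[0]
        t, e = df["time"].to_numpy(), df["event"].to_numpy()
        expected = -sum(np.log((t >= t[i]).sum()) for i in np.flatnonzero(e))
        assert abs(ll0 - expected) < 1e-10

    def test_efron_equals_breslow_without_ties(self):
        df = random_survival_cohort(seed=4, n=80)
        fe = ss.fit_cox(df, ["x1", "x2"], ties="efron")
        fb = ss.fit_cox(df, ["x1", "x2"], ties="breslow")
        np.testing.assert_allclose(fe.beta, fb.beta, atol=1e-10)
        assert abs(fe.log_partial_likelihood - fb.log_partial_likelihood) < 1e-10

    def test_aic_identity(self):
        for seed in (1, 2):
            df = random_survival_cohort(seed=seed, ties=bool(seed % 2))
            fit = ss.fit_cox(df, ["x1", "x2"])
            assert np.isclose(
                fit.aic, -2 * fit.log_partial_likelihood + 2 * len(fit.beta)
            )

    def test_matches_lifelines_with_ties(self):
        lifelines = pytest.importorskip("lifelines")
        df = random_survival_cohort(seed=7, n=120, ties=True)
        fit = ss.fit_cox(df, ["x1", "x2"])
        cph = lifelines.CoxPHFitter().fit(
            df[["time", "event", "x1", "x2"]], "time", "event"
        )
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=5e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=5e-5)

    def test_confounders_expand_to_reference_coded_terms(self, default_cohort):
        fit = ss.fit_cox(default_cohort,
                         ["calgranulin_a", "age", "gender", "therapy", "diagnosis"])
        assert "gender[male]" in fit.columns  # 'female' is the sorted reference
        assert "therapy[TACE]" in fit.columns
        assert sum(c.startswith("diagnosis[") for c in fit.columns) == 4
        for t in ("age", "gender", "therapy", "diagnosis"):
            assert t in fit.terms

    def test_error_cases(self, toy_cohort):
        no_events = toy_cohort.assign(event=0)
        with pytest.raises(ValueError, match="event"):
            ss.fit_cox(no_events, ["x"])
        dup = toy_cohort.assign(x2=toy_cohort["x"] * 2.0)
        with pytest.raises(ValueError, match="rank deficient"):
            ss.fit_cox(dup, ["x", "x2"])
        with pytest.raises(KeyError, match="missing"):
            ss.fit_cox(toy_cohort, ["nope"])


class TestLinearPredictor:
    def test_zero_beta_gives_zero(self, toy_cohort):
        fit = ss.fit_cox(toy_cohort, ["x"])
        fit.beta = np.zeros_like(fit.beta)
        np.testing.assert_array_equal(ss.linear_predictor(fit, toy_cohort), 0.0)

    def test_single_term_identity(self, toy_cohort):
        fit = ss.fit_cox(toy_cohort, ["x"])
        fit.beta = np.array([1.0])
        eta = ss.linear_predictor(fit, toy_cohort)
        centered = toy_cohort["x"] - toy_cohort["x"].mean()
        np.testing.assert_allclose(eta, centered, atol=1e-12)

    def test_mean_zero_contract(self, default_cohort):
        fit = ss.fit_cox(default_cohort, ["sod2", "age", "therapy"])
        eta = ss.linear_predictor(fit, default_cohort)
        assert abs(eta.mean()) < 1e-12

    def test_missing_column_error(self, toy_cohort):
        fit = ss.fit_cox(toy_cohort, ["x"])
        with pytest.raises(KeyError):
            ss.linear_predictor(fit, toy_cohort.drop(columns="x"))


class TestStepwiseAIC:
    def test_single_model_scope_returned_unchanged(self, toy_cohort):
        scope = ModelScope(biomarker="x")
        fit = ss.stepwise_aic(toy_cohort, scope)
        assert fit.terms == ("x",)

    def test_candidate_moves_cover_scope_interactions(self, default_cohort):
        scope = ModelScope(
            biomarker="sod2",
            confounders=("age", "gender", "therapy", "diagnosis"),
            interactions=(("sod2", "therapy"), ("sod2", "diagnosis")),
        )
        assert scope.interaction_terms == ("sod2:therapy", "sod2:diagnosis")
        fit = ss.stepwise_aic(default_cohort, scope)
        assert "sod2" in fit.terms  # forced biomarker main effect
        assert set(fit.terms) <= set(scope.full_terms)

    def test_interaction_requires_scope_membership(self):
        with pytest.raises(ValueError, match="interaction"):
            ModelScope(biomarker="a", confounders=("b",), interactions=(("a", "c"),))

    def test_hierarchy_respected(self, default_cohort):
        scope = ModelScope(
            biomarker="profilin", confounders=("therapy",),
            interactions=(("profilin", "therapy"),),
        )
        fit = ss.stepwise_aic(default_cohort, scope)
        if "profilin:therapy" in fit.terms:
            assert "therapy" in fit.terms

    def test_interaction_overselection_bounded(self):
        """On cohorts generated with a biomarker effect and no interaction,
        AIC keeps a spurious interaction in at most ~20% of seeds."""
        selected = 0
        n_seeds = 50
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed + 500)
            n = 400
            x = rng.normal(size=n)
            therapy = rng.choice(["SIRT", "TACE"], size=n)
            cfg = ss.default_simulation_config(seed=seed)
            times, events = ss.generate_survival_times(0.5 * x, cfg, rng=rng)
            df = pd.DataFrame({"time": times, "event": events, "x": x,
                               "therapy": therapy,
                               "patient_id": np.arange(n)})
            scope = ModelScope(biomarker="x", confounders=("therapy",),
                               interactions=(("x", "therapy"),))
            fit = ss.stepwise_aic(df, scope)
            selected += "x:therapy" in fit.terms
        assert selected <= 0.2 * n_seeds


class TestPHTest:
    def test_hand_computed_schoenfeld_residuals(self):
        # 5 patients, binary covariate, 3 events: residual = x_i - xbar(t_i)
        df = pd.DataFrame({
            "patient_id": list("abcde"),
            "time": [1.0, 2.0, 3.0, 4.0, 5.0],
            "event": [1, 0, 1, 0, 1],
            "x": [1.0, 1.0, 0.0, 1.0, 0.0],
        })
        fit = ss.fit_cox(df, ["x"])
        b = fit.beta[0]
        etimes, resid = ss.schoenfeld_residuals(fit, df)
        w = np.exp(b)
        # risk sets: t=1 {all}, t=3 {c,d,e}, t=5 {e}
        exp1 = 1.0 - 3 * w / (3 * w + 2)
        exp3 = 0.0 - w / (w + 2)
        exp5 = 0.0 - 0.0
        np.testing.assert_allclose(etimes, [1.0, 3.0, 5.0])
        np.testing.assert_allclose(resid[:, 0], [exp1, exp3, exp5], atol=1e-10)

    def test_global_test_detects_gross_violation(self):
        # group 1 has a delayed hazard (zero early, high late): strongly non-PH
        rng = np.random.default_rng(0)
        n = 400
        x = rng.binomial(1, 0.5, n).astype(float)
        time = np.where(x == 1, 20.0 + rng.exponential(5, n), rng.exponential(10, n))
        df = pd.DataFrame({"time": np.maximum(time, 0.01), "event": 1,
                           "x": x, "patient_id": np.arange(n)})
        fit = ss.fit_cox(df, ["x"])
        res = ss.test_ph(fit, df, transform="km")
        assert res.global_p < 0.01

    def test_transform_options(self, default_cohort):
        fit = ss.fit_cox(default_cohort, ["calgranulin_a", "age"])
        for tr in ("km", "identity", "rank"):
            res = ss.test_ph(fit, default_cohort, transform=tr)
            assert 0 <= res.global_p <= 1
            assert res.time_transform == tr
            assert len(res.p_values) == len(fit.columns)
        with pytest.raises(ValueError, match="transform"):
            ss.test_ph(fit, default_cohort, transform="log")

    def test_default_scenario_ph_not_rejected(self, default_cohort):
        """On the proportional-hazards-by-construction scenario, per-biomarker
        global PH p-values are reported and typically not significant."""
        ps = []
        for b in ("calgranulin_a", "sod2", "profilin"):
            fit = ss.fit_cox(default_cohort, [b, "age", "gender", "therapy"])
            ps.append(ss.test_ph(fit, default_cohort).global_p)
        assert all(p > 0.05 for p in ps)
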