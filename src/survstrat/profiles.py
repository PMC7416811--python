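"""Per-patient risk profiles from per-biomarker Cox models.

Each biomarker gets its own confounder-corrected Cox model (optionally
stepwise-selected by AIC); the centred linear predictors are concatenated
column-wise into the patients x biomarkers risk-profile matrix that feeds
consensus clustering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cox import CoxFit, ModelScope, fit_cox, linear_predictor, stepwise_aic

__all__ = ["RiskProfileBuilder", "build_risk_profiles", "default_scopes"]


def default_scopes(biomarkers, confounders=("age", "gender", "therapy", "diagnosis"),
                   interaction_confounders=("therapy", "diagnosis")):
    """One ModelScope per biomarker: confounder main effects plus
    biomarker x therapy and biomarker x primary-tumour interactions."""
    return [
        ModelScope(
            biomarker=b,
            confounders=tuple(confounders),
            interactions=tuple((b, c) for c in interaction_confounders),
        )
        for b in biomarkers
    ]


class RiskProfileBuilder(BaseEstimator, TransformerMixin):
    """Transform a cohort table into a risk-profile matrix.

    Parameters
    ----------
    scopes : list of ModelScope
        One per biomarker.  If None, built from ``biomarkers`` /
        ``confounders`` / ``interaction_confounders``.
    stepwise : bool
        Use bidirectional AIC selection (default) or fit the full scope.
    scaling : {'zscore', 'none'}
        Column scaling of the profile matrix.  Z-scoring puts linear
        predictors from different models on a common scale.

    Attributes
    ----------
    fits_ : dict biomarker -> CoxFit
    mean_, scale_ : per-column statistics used by z-scoring.
    """

    def __init__(self, scopes=None, biomarkers=None,
                 confounders=("age", "gender", "therapy", "diagnosis"),
                 interaction_confounders=("therapy", "diagnosis"),
                 stepwise=True, scaling="zscore", ties="efron",
                 time_col="time", event_col="event"):
        self.scopes = scopes
        self.biomarkers = biomarkers
        self.confounders = confounders
        self.interaction_confounders = interaction_confounders
        self.stepwise = stepwise
        self.scaling = scaling
        self.ties = ties
        self.time_col = time_col
        self.event_col = event_col

    def _resolved_scopes(self):
        if self.scopes is not None:
            return list(self.scopes)
        if self.biomarkers is None:
            raise ValueError("either scopes or biomarkers must be given")
        return default_scopes(self.biomarkers, self.confounders,
                              self.interaction_confounders)

    def fit(self, X: pd.DataFrame, y=None):
        if self.scaling not in ("zscore", "none"):
            raise ValueError("scaling must be 'zscore' or 'none'")
        scopes = self._resolved_scopes()
        self.fits_ = {}
        raw = {}
        for scope in scopes:
            try:
                if self.stepwise:
                    f = stepwise_aic(X, scope, ties=self.ties,
                                     time_col=self.time_col, event_col=self.event_col)
                else:
                    f = fit_cox(X, scope.full_terms, ties=self.ties,
                                time_col=self.time_col, event_col=self.event_col)
                raw[scope.biomarker] = linear_predictor(f, X)
            except Exception as exc:
                raise RuntimeError(
                    f"risk-profile model failed for biomarker '{scope.biomarker}': {exc}"
                ) from exc
            self.fits_[scope.biomarker] = f
        mat = np.column_stack([raw[s.biomarker] for s in scopes])
        sd = mat.std(axis=0, ddof=0)
        if self.scaling == "zscore" and np.any(sd == 0):
            dead = [s.biomarker for s, z in zip(scopes, sd == 0) if z]
            raise ValueError(
                f"degenerate (zero-variance) risk-profile column(s): {dead}"
            )
        self.columns_ = [s.biomarker for s in scopes]
        self.mean_ = mat.mean(axis=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "fits_"):
            raise RuntimeError("RiskProfileBuilder is not fitted")
        mat = np.column_stack(
            [linear_predictor(self.fits_[b], X) for b in self.columns_]
        )
        if self.scaling == "zscore":
            mat = (mat - self.mean_) / self.scale_
        index = X["patient_id"] if "patient_id" in X.columns else X.index
        out = pd.DataFrame(mat, columns=self.columns_, index=pd.Index(index, name="patient_id"))
        out.attrs["scaling"] = self.scaling
        return out


def build_risk_profiles(cohort: pd.DataFrame, scopes, scaling: str = "zscore",
                        stepwise: bool = True, ties: str = "efron",
                        time_col: str = "time", event_col: str = "event"):
    """Fit all per-biomarker models and assemble the risk-profile matrix.

    Returns ``(profiles, fits)``: a patients x biomarkers DataFrame (row
    order matching the cohort) and the dict of fitted CoxFit objects.
    """
    builder = RiskProfileBuilder(scopes=scopes, scaling=scaling, stepwise=stepwise,
                                 ties=ties, time_col=time_col, event_col=event_col)
    builder.fit(cohort)
    return builder.transform(cohort), builder.fits_
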