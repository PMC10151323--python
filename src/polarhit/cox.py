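"""Comparator models: multivariable Cox regression and the perfusion-
abnormality score.

The Cox comparator uses the same clinical features as the network plus the
stress perfusion-deficit extent.  Competing first events are censored at
their event time when fitting a cause-specific model (standard cause-
specific convention); a composite any-MACE fit is available via
``event_kind="MACE"``.  Partial-likelihood maximization (Efron tie
correction) is delegated to lifelines.

``deficit_extent`` is a deliberately simplified surrogate of the clinical
total-perfusion-deficit quantitation: the percentage of polar-map pixels
falling below a threshold fraction of a normal template.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.base import BaseEstimator

from .cohort import EventKind, outcomes_to_arrays
from .grid import TimeGrid

__all__ = ["deficit_extent", "CauseSpecificCox", "fit_cox", "cox_risk"]


def deficit_extent(
    perfusion_map: np.ndarray,
    normal_template: np.ndarray,
    threshold_fraction: float = 0.7,
) -> float:
    """Percent of pixels below ``threshold_fraction`` times the template."""
    perfusion_map = np.asarray(perfusion_map, dtype=float)
    normal_template = np.asarray(normal_template, dtype=float)
    if perfusion_map.shape != normal_template.shape:
        raise ValueError(
            f"map shape {perfusion_map.shape} does not match template "
            f"shape {normal_template.shape}"
        )
    below = perfusion_map < threshold_fraction * normal_template
    return 100.0 * float(below.mean())


class CauseSpecificCox(BaseEstimator):
    """Cause-specific (or composite) Cox proportional-hazards comparator.

    Parameters
    ----------
    event_kind : str
        One of ``"ACS"``, ``"death"``, ``"revascularization"`` or ``"MACE"``
        (composite: any first event counts).
    """

    def __init__(self, event_kind: str = "MACE", penalizer: float = 0.0):
        self.event_kind = event_kind
        self.penalizer = penalizer

    def fit(self, X: pd.DataFrame, y: pd.DataFrame):
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{j}" for j in range(X.shape[1])]
        if X.isna().any().any():
            raise ValueError("Cox comparator requires imputed (complete) features")
        event, days, _ = outcomes_to_arrays(y, TimeGrid())
        if self.event_kind == "MACE":
            observed = event > 0
        else:
            code = {
                "ACS": EventKind.ACS,
                "death": EventKind.DEATH,
                "revascularization": EventKind.REVASCULARIZATION,
            }[self.event_kind]
            observed = event == int(code)
        df = X.reset_index(drop=True).copy()
        df["__time"] = np.maximum(days, 0.5)  # lifelines rejects t == 0
        df["__event"] = observed.astype(int)
        self.fitter_ = CoxPHFitter(penalizer=self.penalizer)
        self.fitter_.fit(df, duration_col="__time", event_col="__event")
        self.coef_ = self.fitter_.params_.copy()
        self.se_ = self.fitter_.standard_errors_.copy()
        self.baseline_cumulative_hazard_ = (
            self.fitter_.baseline_cumulative_hazard_.copy()
        )
        self.feature_names_in_ = list(X.columns)
        return self

    def predict_risk(self, X: pd.DataFrame) -> np.ndarray:
        """Linear predictor beta' x (log partial hazard, uncentered)."""
        if not hasattr(self, "coef_"):
            raise RuntimeError("estimator is not fitted")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=self.feature_names_in_)
        return X[self.feature_names_in_].to_numpy() @ self.coef_.to_numpy()

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Serializable (term, coefficient, SE) and baseline-hazard tables."""
        coefs = pd.DataFrame(
            {"term": self.coef_.index, "coefficient": self.coef_.to_numpy(),
             "se": self.se_.to_numpy()}
        )
        base = self.baseline_cumulative_hazard_.reset_index()
        base.columns = ["time_days", "baseline_cumulative_hazard"]
        return coefs, base


def fit_cox(X: pd.DataFrame, y: pd.DataFrame, event_kind: str = "MACE") -> CauseSpecificCox:
    """Thin functional wrapper over :class:`CauseSpecificCox`."""
    return CauseSpecificCox(event_kind=event_kind).fit(X, y)


def cox_risk(model: CauseSpecificCox, X) -> np.ndarray:
    return model.predict_risk(X)
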