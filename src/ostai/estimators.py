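"""scikit-learn-style estimators over the functional core.

These wrap the screening rules and the index-derivation pipeline in the
fit/predict idiom so they compose with sklearn model selection. ``X`` is
always a cohort-schema DataFrame (see :mod:`ostai.cohort`); the regression
response (the lowest-site T-score) is taken from the T-score columns of
``X`` itself, so ``y`` may be omitted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .cohort import Cohort
from .derivation import derive_index
from .errors import DomainError
from .scoring import DEFAULT_CUTOFF, nof2013_frame, ostai_frame


class OstaiScreen(BaseEstimator, ClassifierMixin):
    """The published OSTAi rule as a (fixed, fit-free) classifier.

    predict(X) is True where 0.2*(weight - age), rounded, falls strictly
    below ``cutoff``; decision_function returns the risk (negated index
    value, higher = more at risk).
    """

    def __init__(self, cutoff: int = DEFAULT_CUTOFF, rounding: str = "nearest"):
        self.cutoff = cutoff
        self.rounding = rounding

    def fit(self, X, y=None):
        self.classes_ = np.array([False, True])
        self.n_features_in_ = X.shape[1]
        return self

    def score_values(self, X: pd.DataFrame) -> np.ndarray:
        return ostai_frame(X, cutoff=self.cutoff, rounding=self.rounding)[
            "ostai_value"
        ].to_numpy()

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return -self.score_values(X)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.score_values(X) < self.cutoff


class Nof2013Screen(BaseEstimator, ClassifierMixin):
    """The NOF 2013 referral recommendation as a (fixed) classifier."""

    def fit(self, X, y=None):
        self.classes_ = np.array([False, True])
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return nof2013_frame(X)["nof2013_positive"].to_numpy(dtype=bool)

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        return self.predict(X).astype(float)


class IndexDeriver(BaseEstimator):
    """Derive an OSTA-style integer index from a cohort frame.

    fit(X) runs the whole pipeline — univariate screen, multivariable OLS,
    integer weighting, AUC-guided item reduction, Youden cutoff — on the
    T-scores carried by ``X``. After fitting, predict(X) gives referral
    decisions with the derived index and cutoff.

    Attributes (post-fit): ``model_`` (reduced IndexModel), ``full_model_``,
    ``univariate_``, ``multivariable_``, ``cutoff_``,
    ``elimination_trace_``, ``auc_full_``, ``auc_reduced_``.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        tol_auc: float = 0.01,
        response: str = "lowest",
        anchor: str = "half_max",
        rounding: str = "nearest",
        stop: str = "step",
    ):
        self.alpha = alpha
        self.tol_auc = tol_auc
        self.response = response
        self.anchor = anchor
        self.rounding = rounding
        self.stop = stop

    def fit(self, X, y=None):
        cohort = X if isinstance(X, Cohort) else Cohort(data=X.reset_index(drop=True))
        result = derive_index(
            cohort,
            alpha=self.alpha,
            tol_auc=self.tol_auc,
            response=self.response,
            anchor=self.anchor,
            rounding=self.rounding,
            stop=self.stop,
        )
        self.result_ = result
        self.model_ = result.reduced_model
        self.full_model_ = result.full_model
        self.univariate_ = result.univariate
        self.multivariable_ = result.multivariable
        self.cutoff_ = result.cutoff
        self.elimination_trace_ = result.reduced_model.elimination_trace
        self.auc_full_ = result.auc_full
        self.auc_reduced_ = result.auc_reduced
        self.n_features_in_ = (X.data if isinstance(X, Cohort) else X).shape[1]
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise DomainError("IndexDeriver is not fitted")

    def score_values(self, X) -> np.ndarray:
        self._check_fitted()
        df = X.data if isinstance(X, Cohort) else X
        return self.model_.scores(df).to_numpy()

    def decision_function(self, X) -> np.ndarray:
        return -self.score_values(X)

    def predict(self, X) -> np.ndarray:
        return self.score_values(X) < self.cutoff_
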