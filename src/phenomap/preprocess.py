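"""Feature screening, mean imputation, and z-scoring.

The chain drops features with >= ``missing_threshold`` missing values
(closed at the boundary), replaces the remaining missing entries by the
observed per-feature mean, and z-scores every column (sample, n-1, SD).
Binary flags go through the same chain as continuous features.

Each step is a scikit-learn transformer operating on patient-indexed
DataFrames with NaN marking missingness; the module-level functions are
thin one-shot wrappers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FeatureFilter",
    "MeanImputer",
    "ZScorer",
    "filter_features",
    "impute_mean",
    "zscore",
]


def _as_frame(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    return X


class FeatureFilter(BaseEstimator, TransformerMixin):
    """Drop features whose missing fraction is >= ``missing_threshold``.

    Fitted attributes: ``kept_features_``, ``discarded_features_``,
    ``missing_fraction_`` (per input feature).
    """

    def __init__(self, missing_threshold: float = 0.40):
        self.missing_threshold = missing_threshold

    def fit(self, X, y=None):
        if not (0.0 < self.missing_threshold <= 1.0):
            raise ValueError("missing_threshold must be in (0, 1]")
        X = _as_frame(X)
        frac = X.isna().mean(axis=0)
        self.missing_fraction_ = frac
        keep = frac < self.missing_threshold
        self.kept_features_ = list(X.columns[keep])
        self.discarded_features_ = list(X.columns[~keep])
        if not self.kept_features_:
            warnings.warn("all features discarded by the missingness filter")
        return self

    def transform(self, X):
        check_is_fitted(self, "kept_features_")
        return _as_frame(X)[self.kept_features_]


class MeanImputer(BaseEstimator, TransformerMixin):
    """Replace missing entries by the observed per-feature mean."""

    def fit(self, X, y=None):
        X = _as_frame(X)
        all_missing = X.columns[X.isna().all(axis=0)]
        if len(all_missing):
            raise ValueError(
                f"feature(s) with no observed values: {list(all_missing)}; "
                "screen them out before imputing"
            )
        self.means_ = X.mean(axis=0)
        return self

    def transform(self, X):
        check_is_fitted(self, "means_")
        return _as_frame(X).fillna(self.means_)


class ZScorer(BaseEstimator, TransformerMixin):
    """Z-score each column using the sample (n-1) standard deviation.

    Zero-variance columns map to all-zeros instead of raising, so constant
    binary flags in small cohorts flow through without NaNs.
    """

    def fit(self, X, y=None):
        X = _as_frame(X)
        self.means_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        self.zero_variance_ = list(X.columns[~(sd > 0)])
        self.scales_ = sd.replace(0.0, 1.0).fillna(1.0)
        return self

    def transform(self, X):
        check_is_fitted(self, "means_")
        X = _as_frame(X)
        out = (X - self.means_) / self.scales_
        if self.zero_variance_:
            out[self.zero_variance_] = 0.0
        return out


def filter_features(features: pd.DataFrame, missing_threshold: float = 0.40):
    """One-shot screen; returns ``(kept_frame, discarded_names)``."""
    f = FeatureFilter(missing_threshold).fit(features)
    return f.transform(features), f.discarded_features_


def impute_mean(features: pd.DataFrame) -> pd.DataFrame:
    return MeanImputer().fit_transform(features)


def zscore(features: pd.DataFrame) -> pd.DataFrame:
    return ZScorer().fit_transform(features)
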