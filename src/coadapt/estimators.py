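"""Scikit-learn-style estimators over the decoding core.

`CSP` is a supervised transformer turning (n_trials, channels, samples)
window arrays into 2m log-normalized-variance features; `CspSvmDecoder`
chains it with the linear soft-margin SVM.  Both follow the sklearn
estimator contract (get_params/set_params, fitted attributes with trailing
underscores, clone-compatible constructors) and compose with pipelines and
model selection.  The session engine uses the same underlying functions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .classification import classify, train
from .csp import compute_csp, extract_features, normalized_covariance

__all__ = ["CSP", "CspSvmDecoder"]


def _as_covariances(X: np.ndarray) -> list:
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError("X must have shape (n_trials, n_channels, n_samples)")
    return [normalized_covariance(X[i]) for i in range(X.shape[0])]


class CSP(TransformerMixin, BaseEstimator):
    """Common-spatial-patterns feature extractor.

    Parameters
    ----------
    n_components : int
        Filters kept from each end of the eigenvalue spectrum (the feature
        dimension is ``2 * n_components``).

    Attributes
    ----------
    filters_ : ndarray (n_channels, n_channels)
        Spatial filters (rows), ordered by descending eigenvalue of the
        class mapped to "right" (the lexicographically larger class label).
    patterns_ : ndarray (n_channels, n_channels)
        Spatial patterns (columns of the pseudo-inverse of ``filters_``).
    eigenvalues_ : ndarray
    selected_ : ndarray
        Indices of the rows used for features.
    classes_ : ndarray of the two class labels.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("CSP requires exactly two classes")
        covs = _as_covariances(X)
        pos, neg = classes[1], classes[0]  # larger label plays the "right" role
        c_pos = np.mean([c.matrix for c, lab in zip(covs, y) if lab == pos], axis=0)
        c_neg = np.mean([c.matrix for c, lab in zip(covs, y) if lab == neg], axis=0)
        filt = compute_csp(c_pos, c_neg, m=self.n_components)
        self.classes_ = classes
        self.filters_ = filt.weights
        self.patterns_ = filt.patterns
        self.eigenvalues_ = filt.eigenvalues
        self.selected_ = filt.selected
        self._filter = filt
        return self

    def transform(self, X):
        check_is_fitted(self, "filters_")
        return np.array([extract_features(c, self._filter).values for c in _as_covariances(X)])


class CspSvmDecoder(ClassifierMixin, BaseEstimator):
    """CSP features followed by a linear soft-margin SVM (cost ``C``).

    ``decision_function`` returns the signed perpendicular distance to the
    separating hyperplane (positive = class ``classes_[1]``), the quantity
    the adaptive feedback thresholds act on.
    """

    def __init__(self, n_components: int = 2, C: float = 1.0):
        self.n_components = n_components
        self.C = C

    def fit(self, X, y):
        y = np.asarray(y)
        self.csp_ = CSP(n_components=self.n_components).fit(X, y)
        feats = self.csp_.transform(X)
        pos = self.csp_.classes_[1]
        labels = ["right" if lab == pos else "left" for lab in y]
        self.model_ = train((feats, labels), C=self.C)
        self.classes_ = self.csp_.classes_
        return self

    def decision_function(self, X):
        check_is_fitted(self, "model_")
        feats = self.csp_.transform(X)
        return np.array([classify(self.model_, f).distance for f in feats])

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d >= 0, self.classes_[1], self.classes_[0])
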