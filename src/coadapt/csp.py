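"""Common spatial patterns: normalized covariances, the projection W, and
log-normalized-variance features.

The CSP projection is obtained by simultaneous diagonalization of the two
class-average normalized covariance matrices: rows of W maximize the
variance ratio between right- and left-hand motor imagery.  Features are
the log of the normalized variances of the most discriminative projected
components (first and last ``m`` rows of Z = W X).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as _la

from .preprocessing import EegWindow

__all__ = [
    "NormalizedCovariance",
    "SpatialFilter",
    "FeatureVector",
    "normalized_covariance",
    "average_covariances",
    "compute_csp",
    "extract_features",
]

RIGHT = "right"
LEFT = "left"


@dataclass
class NormalizedCovariance:
    """Trace-normalized spatial covariance C = X X^T / tr(X X^T) of one window."""

    matrix: np.ndarray
    label: str | None = None
    source_id: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)


@dataclass
class SpatialFilter:
    """CSP projection.

    ``weights`` rows are spatial filters ordered by descending right-class
    eigenvalue; ``selected`` indexes the first and last ``m`` rows;
    ``eigenvalues`` are the per-row right-class generalized eigenvalues in
    [0, 1].  Spatial *patterns* (topographies) are the columns of
    ``weights``' inverse.
    """

    weights: np.ndarray
    eigenvalues: np.ndarray
    selected: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.weights.shape[1]

    @property
    def patterns(self) -> np.ndarray:
        """Columns are the spatial patterns (topographies) of each component."""
        return np.linalg.pinv(self.weights)


@dataclass
class FeatureVector:
    """Log-normalized variances of the selected CSP components."""

    values: np.ndarray
    label: str | None = None
    distance: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


def normalized_covariance(window: EegWindow | np.ndarray, label: str | None = None, source_id: int = 0) -> NormalizedCovariance:
    """C = X X^T / tr(X X^T): symmetric, PSD, unit trace.

    Windows are not mean-centered first; the band-passed signal is already
    ~zero-mean and the plain outer-product form keeps features computable
    from the stored covariance alone.
    """
    if isinstance(window, EegWindow):
        X = window.data
        if label is None:
            label = window.label
    else:
        X = np.asarray(window, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("window must be a (channels x samples) matrix with >= 2 samples")
    C = X @ X.T
    tr = np.trace(C)
    if tr <= 0:
        raise ValueError("degenerate window: zero total power, covariance undefined")
    C = C / tr
    C = 0.5 * (C + C.T)  # kill asymmetry from round-off
    return NormalizedCovariance(matrix=C, label=label, source_id=source_id)


def average_covariances(bank: list[NormalizedCovariance], label: str) -> np.ndarray:
    """Unweighted elementwise mean of all stored matrices of one class."""
    mats = [c.matrix for c in bank if c.label == label]
    if not mats:
        raise ValueError(f"no covariance matrices of class {label!r} in the bank")
    return np.mean(mats, axis=0)


def compute_csp(c_right: np.ndarray, c_left: np.ndarray, m: int = 2) -> SpatialFilter:
    """Simultaneously diagonalize two class-mean covariances.

    Solves the generalized symmetric eigenproblem
    ``c_right w = lambda (c_right + c_left) w``; the eigenvalues lie in
    [0, 1] and the per-row eigenvalues of the two classes sum to one.  Rows
    of W are sorted by descending right-class eigenvalue and sign-fixed so
    the largest-magnitude entry of each row is positive.

    Parameters
    ----------
    c_right, c_left : ndarray (channels x channels)
        Symmetric PSD class means; their sum must be positive definite.
    m : int
        Components kept from each end of the spectrum (default 2, i.e. the
        feature vector has 2m entries).
    """
    c_right = np.asarray(c_right, dtype=float)
    c_left = np.asarray(c_left, dtype=float)
    if c_right.shape != c_left.shape or c_right.ndim != 2 or c_right.shape[0] != c_right.shape[1]:
        raise ValueError("class covariances must be square matrices of equal size")
    n = c_right.shape[0]
    composite = c_right + c_left
    # eigh(a, b) needs b positive definite; report the offending dimension.
    comp_eig, comp_vec = np.linalg.eigh(0.5 * (composite + composite.T))
    bad = np.nonzero(comp_eig < 1e-12 * max(comp_eig.max(), 1.0))[0]
    if bad.size:
        channels = sorted({int(np.argmax(np.abs(comp_vec[:, i]))) for i in bad})
        raise np.linalg.LinAlgError(
            f"composite covariance is rank deficient in dimension(s) {channels}"
        )
    vals, vecs = _la.eigh(0.5 * (c_right + c_right.T), 0.5 * (composite + composite.T))
    order = np.argsort(vals)[::-1]
    vals = np.clip(vals[order], 0.0, 1.0)
    W = vecs[:, order].T
    # sign convention: largest-|entry| of each filter row positive
    for i in range(n):
        j = int(np.argmax(np.abs(W[i])))
        if W[i, j] < 0:
            W[i] = -W[i]
    m = min(m, n // 2) if n >= 2 else 1
    selected = np.concatenate([np.arange(m), np.arange(n - m, n)])
    return SpatialFilter(weights=W, eigenvalues=vals, selected=selected)


def extract_features(
    window_or_cov: EegWindow | NormalizedCovariance | np.ndarray,
    filt: SpatialFilter,
) -> FeatureVector:
    """Log-normalized variances of the selected CSP components.

    For selected row p, ``v_p = (W C W^T)_pp`` and the feature is
    ``log(v_p / sum_q v_q)`` over the selected components only, so the
    result is identical whether computed from the raw window or from its
    stored normalized covariance (the trace factor cancels).
    """
    label = None
    if isinstance(window_or_cov, EegWindow):
        cov = normalized_covariance(window_or_cov)
        C = cov.matrix
        label = window_or_cov.label
    elif isinstance(window_or_cov, NormalizedCovariance):
        C = window_or_cov.matrix
        label = window_or_cov.label
    else:
        C = np.asarray(window_or_cov, dtype=float)
    if C.shape[0] != filt.n_channels:
        raise ValueError(
            f"covariance dimension {C.shape[0]} does not match filter "
            f"dimension {filt.n_channels}"
        )
    Wsel = filt.weights[filt.selected]
    v = np.einsum("ij,jk,ik->i", Wsel, C, Wsel)
    total = v.sum()
    if total <= 0:
        raise ValueError("degenerate input: zero total variance in selected components")
    return FeatureVector(values=np.log(v / total), label=label)
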