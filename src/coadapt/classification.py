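"""Linear soft-margin classification and the remappable training store.

The decoder is a linear SVM with misclassification cost C = 1 (libsvm via
scikit-learn).  Decisions carry the signed perpendicular distance to the
separating hyperplane, which the adaptation layer uses both to gate
feedback and to rank portions for selective updating.

The training store is a fixed-capacity bank of per-portion normalized
covariance matrices plus their current feature vectors.  Holding
covariances (not raw windows) is exactly sufficient: after a spatial-filter
update the whole set is remapped by recomputing features from the stored
covariances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .csp import (
    LEFT,
    RIGHT,
    FeatureVector,
    NormalizedCovariance,
    SpatialFilter,
    extract_features,
)

__all__ = [
    "ClassifierModel",
    "Decision",
    "StoreEntry",
    "TrainingStore",
    "train",
    "classify",
    "remap_store",
    "replace_oldest",
]


@dataclass
class ClassifierModel:
    """Trained linear decision rule: sign(w . f + b) -> {right (+), left (-)}."""

    weight_vector: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        self.weight_vector = np.asarray(self.weight_vector, dtype=float)
        if not np.all(np.isfinite(self.weight_vector)) or not np.isfinite(self.bias):
            raise ValueError("classifier parameters must be finite")

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.weight_vector))


@dataclass
class Decision:
    """Predicted class plus signed perpendicular distance to the boundary.

    Positive distance means the "right" side of the hyperplane; the sign is
    always consistent with the predicted class (ties at exactly 0 go to
    "right").
    """

    predicted: str
    distance: float


@dataclass
class StoreEntry:
    covariance: NormalizedCovariance
    label: str
    feature: FeatureVector
    age: int


@dataclass
class TrainingStore:
    """Fixed-capacity, class-aware store of training portions.

    ``capacity`` defaults to the T-module portion count (238).  ``age`` is a
    monotone insertion counter used by the oldest-first replacement policy.
    """

    capacity: int = 238
    entries: list[StoreEntry] = field(default_factory=list)
    _counter: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def class_count(self, label: str) -> int:
        return sum(1 for e in self.entries if e.label == label)

    def add(self, covariance: NormalizedCovariance, label: str, feature: FeatureVector) -> None:
        if len(self.entries) >= self.capacity:
            raise ValueError("store is full; use replace_oldest")
        self.entries.append(StoreEntry(covariance, label, feature, self._counter))
        self._counter += 1

    def features(self) -> np.ndarray:
        return np.array([e.feature.values for e in self.entries])

    def labels(self) -> list[str]:
        return [e.label for e in self.entries]


def train(store: TrainingStore | tuple[np.ndarray, list[str]], C: float = 1.0) -> ClassifierModel:
    """Fit the linear soft-margin SVM (cost parameter C = 1) on the store.

    Deterministic for fixed input: libsvm with a fixed tolerance and no
    randomized components for the linear two-class case.
    """
    if isinstance(store, TrainingStore):
        X, y = store.features(), store.labels()
    else:
        X, y = store
    X = np.asarray(X, dtype=float)
    labels = set(y)
    if len(labels) < 2:
        raise ValueError("cannot train: training set contains a single class")
    if not labels <= {RIGHT, LEFT}:
        raise ValueError(f"unknown labels {labels - {RIGHT, LEFT}}")
    # numeric y fixes the sign convention: +1 = right, -1 = left
    y_num = np.array([1 if lab == RIGHT else -1 for lab in y])
    svm = SVC(kernel="linear", C=C, tol=1e-6)
    svm.fit(X, y_num)
    w = svm.coef_.ravel()
    b = float(svm.intercept_[0])
    return ClassifierModel(weight_vector=w, bias=b)


def classify(model: ClassifierModel, feature: FeatureVector | np.ndarray) -> Decision:
    """Apply the decision rule; distance = (w.f + b) / ||w||.

    A feature exactly on the boundary (distance 0) is assigned to "right"
    — a fixed, documented tie-break.
    """
    f = feature.values if isinstance(feature, FeatureVector) else np.asarray(feature, dtype=float)
    if f.shape[0] != model.weight_vector.shape[0]:
        raise ValueError(
            f"feature dimension {f.shape[0]} does not match model "
            f"dimension {model.weight_vector.shape[0]}"
        )
    raw = float(model.weight_vector @ f + model.bias)
    dist = raw / model.norm
    predicted = RIGHT if dist >= 0 else LEFT
    return Decision(predicted=predicted, distance=dist)


def remap_store(store: TrainingStore, filt: SpatialFilter) -> TrainingStore:
    """Recompute every entry's feature from its stored covariance under a new W.

    Labels and ages are untouched; remapping is idempotent and only the last
    filter applied matters.  Mutates and returns the store.
    """
    for e in store.entries:
        e.feature = extract_features(e.covariance, filt)
    return store


def replace_oldest(
    store: TrainingStore,
    incoming: list[tuple[NormalizedCovariance, str]],
    filt: SpatialFilter,
) -> TrainingStore:
    """Insert new portions by evicting the oldest stored entry of the same class.

    Keeps the store size and per-class counts constant, matching the
    replacement-not-addition policy that holds retraining cost flat.  If
    more portions of one class arrive than that class holds, the surplus
    oldest incoming ones are dropped with a warning (newest kept).
    """
    by_class: dict[str, list[tuple[NormalizedCovariance, str]]] = {}
    for cov, lab in incoming:
        if lab not in (RIGHT, LEFT):
            raise ValueError(f"unknown label {lab!r}")
        by_class.setdefault(lab, []).append((cov, lab))
    for lab, items in by_class.items():
        cap = store.class_count(lab)
        if len(items) > cap:
            warnings.warn(
                f"{len(items) - cap} incoming {lab!r} portions exceed the "
                f"per-class capacity {cap}; keeping the newest",
                stacklevel=2,
            )
            items = items[len(items) - cap :]
        for cov, _ in items:
            oldest_i = min(
                (i for i, e in enumerate(store.entries) if e.label == lab),
                key=lambda i: store.entries[i].age,
            )
            del store.entries[oldest_i]
            store.add(cov, lab, extract_features(cov, filt))
    return store
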