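"""The U-repetition update cycle: adaptive feedback thresholds, selection of
the best balanced portions (B/BB lists), covariance banking, spatial-filter
and classifier updates, and cue-imbalance scheduling.

The adaptation scheme is selective: only portions that were classified
correctly *and* lay beyond the adaptive distance threshold enter the update
(B list), and the B list is balanced across classes by dropping the
weakest majority-class portions (BB list).  The spatial filter is then
recomputed from the running average of every covariance selected since the
start of the session, which progressively stabilizes W, while the SVM
training set is updated by replacement to keep retraining cost constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classification import (
    ClassifierModel,
    Decision,
    TrainingStore,
    remap_store,
    replace_oldest,
    train,
)
from .csp import (
    LEFT,
    RIGHT,
    NormalizedCovariance,
    SpatialFilter,
    average_covariances,
    compute_csp,
)

__all__ = [
    "ThresholdState",
    "PortionRecord",
    "ImbalanceSchedule",
    "CovarianceBank",
    "update_threshold",
    "gate_feedback",
    "select_best",
    "balance_best",
    "update_spatial_filter",
    "update_classifier",
    "schedule_arrows",
    "u_accuracy",
]


@dataclass
class ThresholdState:
    """Per-class adaptive feedback thresholds.

    Each threshold starts at 0 and tracks ``fraction`` (default 0.6) of the
    running mean absolute distance of *correctly classified* portions of
    that class, accumulated from the start of the session.  Frozen in the
    C phase.
    """

    fraction: float = 0.6
    sums: dict[str, float] = field(default_factory=lambda: {RIGHT: 0.0, LEFT: 0.0})
    counts: dict[str, int] = field(default_factory=lambda: {RIGHT: 0, LEFT: 0})
    frozen: bool = False

    def threshold(self, label: str) -> float:
        n = self.counts[label]
        return self.fraction * self.sums[label] / n if n > 0 else 0.0

    def reset(self) -> None:
        self.sums = {RIGHT: 0.0, LEFT: 0.0}
        self.counts = {RIGHT: 0, LEFT: 0}
        self.frozen = False


@dataclass
class PortionRecord:
    """Bookkeeping for one classified portion of a U (or C) repetition."""

    covariance: NormalizedCovariance
    cue: str
    decision: Decision
    above_threshold: bool = False
    window: object | None = None  # optional raw EegWindow for spectral analyses

    @property
    def correct(self) -> bool:
        return self.decision.predicted == self.cue


@dataclass
class ImbalanceSchedule:
    """Cue counts and presentation order for one U repetition."""

    arrows_right: int
    arrows_left: int
    order: list[str] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.arrows_right + self.arrows_left


@dataclass
class CovarianceBank:
    """All covariance matrices selected since the start of the session:
    the T-module portions plus every BB portion.  Grows monotonically;
    cleared only when T is reset."""

    items: list[NormalizedCovariance] = field(default_factory=list)

    def extend(self, covs: list[NormalizedCovariance]) -> None:
        self.items.extend(covs)

    def class_mean(self, label: str) -> np.ndarray:
        return average_covariances(self.items, label)

    def count(self, label: str | None = None) -> int:
        if label is None:
            return len(self.items)
        return sum(1 for c in self.items if c.label == label)

    def clear(self) -> None:
        self.items = []


def update_threshold(state: ThresholdState, record: PortionRecord) -> ThresholdState:
    """Fold one portion into the running threshold means.

    Only correct classifications count; a misclassified portion leaves the
    state untouched.  Raises if the state is frozen (C phase).
    """
    if state.frozen:
        raise RuntimeError("threshold state is frozen; no updates allowed in C")
    if record.correct:
        state.sums[record.cue] += abs(record.decision.distance)
        state.counts[record.cue] += 1
    return state


def gate_feedback(state: ThresholdState, record: PortionRecord) -> bool:
    """True iff the portion is "distant enough" to earn feedback.

    Strictly greater than the adaptive threshold of the *predicted* class;
    at session start both thresholds are 0, so any nonzero distance passes.
    The outcome is stored on the record.
    """
    thr = state.threshold(record.decision.predicted)
    record.above_threshold = abs(record.decision.distance) > thr
    return record.above_threshold


def select_best(records: list[PortionRecord]) -> list[PortionRecord]:
    """The B list: portions both correctly classified and above threshold,
    in their original order.  May be empty (then no update happens)."""
    return [r for r in records if r.correct and r.above_threshold]


def balance_best(b: list[PortionRecord]) -> list[PortionRecord]:
    """Reduce B to the best *balanced* list (BB): equal class counts.

    Majority-class portions with the smallest absolute distance from the
    hyperplane are removed first, keeping the clearest examples.
    """
    rights = [r for r in b if r.cue == RIGHT]
    lefts = [r for r in b if r.cue == LEFT]
    k = min(len(rights), len(lefts))

    def keep_strongest(group: list[PortionRecord]) -> set[int]:
        idx = sorted(range(len(group)), key=lambda i: abs(group[i].decision.distance), reverse=True)[:k]
        return set(idx)

    keep_r = keep_strongest(rights)
    keep_l = keep_strongest(lefts)
    out: list[PortionRecord] = []
    ri = li = 0
    for r in b:
        if r.cue == RIGHT:
            if ri in keep_r:
                out.append(r)
            ri += 1
        else:
            if li in keep_l:
                out.append(r)
            li += 1
    return out


def update_spatial_filter(
    bank: CovarianceBank,
    bb: list[PortionRecord],
    current: SpatialFilter,
    m: int = 2,
) -> SpatialFilter:
    """Append the BB covariances to the bank and recompute W from its means.

    W_new is the CSP of the per-class unweighted means over the *whole*
    bank (T portions plus every BB so far), so each selected portion counts
    equally and W stabilizes as the bank grows.  An empty BB leaves both the
    bank and W unchanged.
    """
    if not bb:
        return current
    bank.extend([r.covariance for r in bb])
    return compute_csp(bank.class_mean(RIGHT), bank.class_mean(LEFT), m=m)


def update_classifier(
    store: TrainingStore,
    filter_new: SpatialFilter,
    bb: list[PortionRecord],
) -> ClassifierModel:
    """Remap the training set under W_new, swap in the BB portions, retrain.

    The three-step update: (i) recompute every stored feature from its
    covariance under ``filter_new``; (ii) insert each BB portion by evicting
    the oldest same-class entry; (iii) refit the SVM on the updated store.
    """
    remap_store(store, filter_new)
    if bb:
        replace_oldest(store, [(r.covariance, r.cue) for r in bb], filter_new)
    return train(store)


def schedule_arrows(
    mis_right: int,
    mis_left: int,
    arrows_per_u: int = 10,
    rng: np.random.Generator | None = None,
) -> ImbalanceSchedule:
    """Cue split for the next U repetition, biased toward the weaker class.

    The share of arrows given to a class follows its share of the previous
    repetition's misclassifications, floored to an integer and clipped to
    [3, 7] out of 10 (scaled for other ``arrows_per_u``); no
    misclassifications at all gives the balanced 5:5.  Presentation order
    is a seeded random permutation.
    """
    if mis_right < 0 or mis_left < 0:
        raise ValueError("misclassification counts must be non-negative")
    total = mis_right + mis_left
    half = arrows_per_u // 2
    lo = max(arrows_per_u - 7 * arrows_per_u // 10, int(np.ceil(0.3 * arrows_per_u)))
    hi = arrows_per_u - lo
    if total == 0:
        n_right = arrows_per_u - half
    else:
        n_right = int(np.floor(arrows_per_u * mis_right / total))
        n_right = int(np.clip(n_right, lo, hi))
    n_left = arrows_per_u - n_right
    order = [RIGHT] * n_right + [LEFT] * n_left
    if rng is not None:
        rng.shuffle(order)
    return ImbalanceSchedule(arrows_right=n_right, arrows_left=n_left, order=order)


def u_accuracy(records: list[PortionRecord]) -> float:
    """Fraction of correctly classified portions; threshold-independent."""
    if not records:
        raise ValueError("accuracy undefined for an empty repetition")
    return sum(r.correct for r in records) / len(records)
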