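"""Session evaluation statistics.

Accuracy alone is not interpretable when cue presentation is imbalanced, so
every session report pairs the mean accuracy with its confusion-matrix
chance level p0, an adjusted-accuracy confidence lower bound, a
significance flag, and the Wolpaw information transfer rate.  Topographic
r-squared maps quantify how strongly band power separates the two imagery
tasks per channel and frequency bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from scipy.stats import norm as _norm

from .csp import LEFT, RIGHT
from .preprocessing import EegWindow

__all__ = [
    "ConfusionMatrix",
    "AccuracyReport",
    "R2Map",
    "chance_level",
    "lower_confidence_bound",
    "itr",
    "peak_accuracy_curve",
    "band_powers",
    "r2_map",
    "accuracy_report",
    "summarize_session",
]


@dataclass
class ConfusionMatrix:
    """Two-class counts with "right" as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @classmethod
    def from_labels(cls, cues: list[str], predictions: list[str]) -> "ConfusionMatrix":
        tp = fn = fp = tn = 0
        for c, p in zip(cues, predictions, strict=True):
            if c == RIGHT:
                tp += p == RIGHT
                fn += p == LEFT
            else:
                tn += p == LEFT
                fp += p == RIGHT
        return cls(tp=tp, fn=fn, fp=fp, tn=tn)


@dataclass
class AccuracyReport:
    mean_accuracy: float
    peak_accuracy: float | None
    p0: float
    p_hat: float
    p_lower: float
    significant: bool
    itr_bits_per_min: float
    alpha: float = 0.05


def chance_level(cm: ConfusionMatrix) -> float:
    """Chance accuracy from the marginals of the confusion matrix:

    p0 = [(TP+FN)(TP+FP) + (FP+TN)(FN+TN)] / N^2,

    the accuracy a classifier matching the empirical label/prediction
    marginals would reach by agreement alone.
    """
    n = cm.n
    if n < 1:
        raise ValueError("chance level undefined for an empty confusion matrix")
    return ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.fp + cm.tn) * (cm.fn + cm.tn)) / n**2


def lower_confidence_bound(cm: ConfusionMatrix, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Adjusted accuracy, its confidence lower bound, and significance.

    p_hat = (TP+TN+2)/(N+4) is the (+2/+4 adjusted) mean accuracy;
    p_l = p_hat - z_{1-alpha/2} sqrt(p_hat (1-p_hat) / (N+4)).
    The accuracy is significantly above chance iff p0 < p_l.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    n = cm.n
    if n < 1:
        raise ValueError("confidence bound undefined for an empty confusion matrix")
    p_hat = (cm.tp + cm.tn + 2) / (n + 4)
    z = _norm.ppf(1 - alpha / 2)
    p_lower = p_hat - z * np.sqrt(p_hat * (1 - p_hat) / (n + 4))
    significant = chance_level(cm) < p_lower
    return p_hat, p_lower, significant


def itr(accuracy: float, n_classes: int = 2, decisions_per_min: float = 120.0) -> float:
    """Wolpaw information transfer rate in bits/min.

    bits/decision = log2 n + p log2 p + (1-p) log2((1-p)/(n-1)), with the
    0 log 0 = 0 limit at p in {0, 1}.  The default decision rate of 120/min
    reflects one classification every 0.5 s.  Accuracies below chance return
    0 with a warning (the formula turns back up below chance, which is not
    meaningful for a confusion-free report).
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    p = accuracy
    n = n_classes
    if p < 1.0 / n:
        warnings.warn("accuracy below chance; reporting ITR = 0", stacklevel=2)
        return 0.0
    bits = np.log2(n)
    if p > 0:
        bits += p * np.log2(p)
    if p < 1:
        bits += (1 - p) * np.log2((1 - p) / (n - 1))
    return float(bits * decisions_per_min)


def peak_accuracy_curve(
    offsets: list[float], correct: list[bool]
) -> tuple[dict[float, float], float]:
    """Per-time-point accuracy across trials and its peak.

    Groups decisions by their window offset within the trial, returns the
    fraction correct at each offset plus the maximum (the peak accuracy).
    """
    cells: dict[float, list[bool]] = {}
    for o, c in zip(offsets, correct, strict=True):
        cells.setdefault(round(float(o), 6), []).append(c)
    curve = {o: float(np.mean(v)) for o, v in sorted(cells.items())}
    if not curve:
        raise ValueError("no decisions to build an accuracy curve from")
    return curve, max(curve.values())


def band_powers(
    window: EegWindow,
    sample_rate: float,
    band: tuple[float, float] = (8.0, 30.0),
    bin_hz: float = 2.0,
) -> np.ndarray:
    """Per-channel band power in ``bin_hz``-wide bins tiling ``band``.

    One modified periodogram (Blackman-Harris window) per portion; the
    power of a bin is the sum of periodogram ordinates whose frequencies
    fall in the half-open interval [lo, hi).  Returns (channels x bins).
    """
    lo, hi = band
    edges = np.arange(lo, hi + bin_hz / 2, bin_hz)
    freqs, psd = _sig.periodogram(window.data, fs=sample_rate, window="blackmanharris", axis=1)
    nbins = len(edges) - 1
    out = np.empty((window.n_channels, nbins))
    for b in range(nbins):
        sel = (freqs >= edges[b]) & (freqs < edges[b + 1])
        out[:, b] = psd[:, sel].sum(axis=1)
    return out


@dataclass
class R2Map:
    """Grid of r-squared values, (channels x frequency bins)."""

    values: np.ndarray
    bin_edges: np.ndarray
    condition: str = ""

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def r2_map(
    windows: list[EegWindow],
    sample_rate: float,
    band: tuple[float, float] = (8.0, 30.0),
    bin_hz: float = 2.0,
    condition: str = "",
) -> R2Map:
    """Topographic map of class discriminability in band power.

    For every (channel, bin) cell, r^2 is the squared Pearson correlation
    between the per-portion power and a +/-1 class indicator — the fraction
    of power variance explained by the imagery task.  Cells with constant
    power across portions are set to 0 with a warning.
    """
    labeled = [w for w in windows if w.label in (RIGHT, LEFT)]
    n_r = sum(1 for w in labeled if w.label == RIGHT)
    n_l = len(labeled) - n_r
    if n_r < 2 or n_l < 2:
        raise ValueError("r2_map needs at least 2 portions per class")
    powers = np.stack([band_powers(w, sample_rate, band, bin_hz) for w in labeled])  # (n, ch, bins)
    y = np.array([1.0 if w.label == RIGHT else -1.0 for w in labeled])
    yc = y - y.mean()
    pc = powers - powers.mean(axis=0)
    cov = np.einsum("n,nij->ij", yc, pc)
    denom = np.sqrt((yc**2).sum() * (pc**2).sum(axis=0))
    values = np.zeros(powers.shape[1:])
    zero = denom == 0
    if zero.any():
        warnings.warn("constant power in some (channel, bin) cells; r^2 set to 0", stacklevel=2)
    nz = ~zero
    values[nz] = (cov[nz] / denom[nz]) ** 2
    lo, hi = band
    edges = np.arange(lo, hi + bin_hz / 2, bin_hz)
    return R2Map(values=values, bin_edges=edges, condition=condition)


def accuracy_report(
    cues: list[str],
    predictions: list[str],
    offsets: list[float] | None = None,
    alpha: float = 0.05,
    decisions_per_min: float = 120.0,
) -> AccuracyReport:
    """Bundle the per-session statistics from one stream of decisions."""
    cm = ConfusionMatrix.from_labels(cues, predictions)
    p0 = chance_level(cm)
    p_hat, p_lower, significant = lower_confidence_bound(cm, alpha)
    peak = None
    if offsets is not None:
        _, peak = peak_accuracy_curve(offsets, [c == p for c, p in zip(cues, predictions, strict=True)])
    acc = cm.accuracy
    rate = itr(acc, 2, decisions_per_min) if acc >= 0.5 else 0.0
    return AccuracyReport(
        mean_accuracy=acc,
        peak_accuracy=peak,
        p0=p0,
        p_hat=p_hat,
        p_lower=p_lower,
        significant=significant,
        itr_bits_per_min=rate,
        alpha=alpha,
    )


def summarize_session(events, alpha: float = 0.05, decisions_per_min: float = 120.0) -> dict:
    """One summary row per session, mirroring the standard report layout:
    U-phase peak/mean accuracy, chance level, significance and ITR, plus
    the same statistics for the C phase if it was reached.

    Only U repetitions following the *last* T (calibration reset) enter the
    U statistics; C statistics pool scored decisions (reached targets in
    full, the first 30 s of timeouts).
    """
    last_t = max((i for i, e in enumerate(events) if e.module == "T"), default=-1)
    row: dict = {}
    u = [e for e in events[last_t + 1 :] if e.module == "U" and e.predicted is not None]
    if u:
        rep = accuracy_report(
            [e.cue for e in u],
            [e.predicted for e in u],
            offsets=[e.offset_s for e in u],
            alpha=alpha,
            decisions_per_min=decisions_per_min,
        )
        row.update(
            u_peak_pct=100 * rep.peak_accuracy,
            u_mean_pct=100 * rep.mean_accuracy,
            u_p0_pct=100 * rep.p0,
            u_significant=rep.significant,
            u_itr_bits_per_min=rep.itr_bits_per_min,
        )
    c = [e for e in events if e.module == "C" and e.scored and e.predicted is not None]
    if c:
        rep = accuracy_report(
            [e.cue for e in c],
            [e.predicted for e in c],
            alpha=alpha,
            decisions_per_min=decisions_per_min,
        )
        row.update(
            c_mean_pct=100 * rep.mean_accuracy,
            c_p0_pct=100 * rep.p0,
            c_significant=rep.significant,
            c_itr_bits_per_min=rep.itr_bits_per_min,
        )
    return row
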