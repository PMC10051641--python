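"""Evaluation metrics: Dice overlap, binary accuracy, F1, ROC/EER.

The F1-score is computed directly from confusion counts as
``2*TP / (2*TP + FP + FN)``, algebraically identical to the harmonic mean of
precision and recall where both are defined.  The ROC/EER utility sweeps a
distance threshold over genuine/impostor score distributions and is used to
calibrate the verification threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(predictions, labels) -> ConfusionCounts:
    """Count TP/FP/FN/TN for boolean predictions against boolean labels."""
    p = np.asarray(predictions, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if p.shape != y.shape:
        raise ValueError("predictions and labels must have the same length")
    return ConfusionCounts(
        tp=int(np.sum(p & y)), fp=int(np.sum(p & ~y)),
        fn=int(np.sum(~p & y)), tn=int(np.sum(~p & ~y)),
    )


def dice_coefficient(p: np.ndarray, y: np.ndarray) -> float:
    """Overlap of a (possibly soft) prediction with a binary mask:
    ``2|P∩Y| / (|P| + |Y|)``, in [0, 1]; 1 when both masks are empty.

    Soft predictions use the elementwise product as the intersection.
    """
    p = np.asarray(p, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {y.shape}")
    denom = p.sum() + y.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (p * y).sum() / denom)


def dice_loss(p: np.ndarray, y: np.ndarray) -> float:
    """1 - Dice; zero iff the overlap is perfect."""
    return 1.0 - dice_coefficient(p, y)


def f1_score(c: ConfusionCounts) -> float:
    """F = 2*TP / (2*TP + FP + FN); 0 (with a warning) when undefined."""
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        log.warning("F1 undefined (no positives anywhere); reporting 0")
        return 0.0
    return 2.0 * c.tp / denom


def binary_accuracy(predictions, labels) -> float:
    """Fraction of agreeing entries; serves pixels and pairs alike."""
    p = np.asarray(predictions)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError("length mismatch")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.mean((p > 0.5) == (y > 0.5)))


def roc_and_eer(distances, labels):
    """Threshold sweep over match distances.

    ``labels``: 1 = genuine (accepted when distance <= tau), 0 = impostor.
    Returns (roc, eer, tau_at_eer) where roc is an array of rows
    (tau, FAR, FRR) and the EER is linearly interpolated between the
    bracketing sweep points.
    """
    d = np.asarray(distances, dtype=float)
    y = np.asarray(labels).astype(bool)
    if d.shape != y.shape:
        raise ValueError("distances and labels must align")
    if y.all() or (~y).all():
        raise ValueError("need at least one genuine and one impostor")
    genuine = d[y]
    impostor = d[~y]
    taus = np.unique(np.concatenate([[-np.inf], np.unique(d), [np.inf]]))
    far = np.array([(impostor <= t).mean() for t in taus])  # false accepts
    frr = np.array([(genuine > t).mean() for t in taus])    # false rejects
    roc = np.column_stack([taus, far, frr])

    diff = far - frr  # increases with tau from -1 to +1
    k = int(np.searchsorted(diff > 0, True))
    if k == 0:
        eer, tau = float(far[0]), float(taus[0])
    else:
        d0, d1 = diff[k - 1], diff[k]
        w = 0.0 if d1 == d0 else -d0 / (d1 - d0)
        eer = float((1 - w) * (far[k - 1] + frr[k - 1]) / 2 + w * (far[k] + frr[k]) / 2)
        t0 = taus[k - 1] if np.isfinite(taus[k - 1]) else taus[k]
        t1 = taus[k] if np.isfinite(taus[k]) else taus[k - 1]
        tau = float((1 - w) * t0 + w * t1)
    return roc, eer, tau


def calibrate_threshold(distances, labels) -> tuple[float, float]:
    """Distance threshold maximising F1 on (distances, labels); returns
    (tau, best F1).  Genuine pairs are the positive class."""
    d = np.asarray(distances, dtype=float)
    y = np.asarray(labels).astype(bool)
    best_tau, best_f1 = float(np.median(d)), -1.0
    for t in np.unique(d):
        c = confusion_counts(d <= t, y)
        f = f1_score(c)
        if f > best_f1:
            best_tau, best_f1 = float(t), f
    return best_tau, best_f1
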