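"""Binary-classification metrics (accuracy, F1, loss, MCC)."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


def mcc(tp: float, fp: float, tn: float, fn: float) -> float:
    """Matthews correlation coefficient; 0 on degenerate confusion matrices."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def f1_score(tp: float, fp: float, fn: float) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


@dataclass
class MetricsReport:
    accuracy: float
    f1: float
    loss: float
    mcc: float
    granularity: str = "per-base"  # per-base | per-entry | per-pair
    balanced_accuracy: float | None = None

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "loss": self.loss,
            "mcc": self.mcc,
            "granularity": self.granularity,
        }


def binary_report(
    probs: np.ndarray,
    truth: np.ndarray,
    threshold: float = 0.5,
    granularity: str = "per-base",
) -> MetricsReport:
    """Metrics for probabilistic predictions against binary truth."""
    probs = np.asarray(probs, dtype=float).ravel()
    truth = np.asarray(truth, dtype=float).ravel()
    if probs.shape != truth.shape:
        raise ValueError("prediction/truth shape mismatch")
    pred = probs >= threshold
    t = truth >= 0.5
    tp = float(np.sum(pred & t))
    fp = float(np.sum(pred & ~t))
    tn = float(np.sum(~pred & ~t))
    fn = float(np.sum(~pred & t))
    eps = 1e-12
    loss = float(
        -np.mean(
            truth * np.log(probs + eps) + (1 - truth) * np.log(1 - probs + eps)
        )
    )
    n = len(truth)
    pos, neg = tp + fn, tn + fp
    bal = (
        0.5 * (tp / pos + tn / neg) if pos > 0 and neg > 0 else None
    )
    return MetricsReport(
        accuracy=(tp + tn) / n if n else 0.0,
        f1=f1_score(tp, fp, fn),
        loss=loss,
        mcc=mcc(tp, fp, tn, fn),
        granularity=granularity,
        balanced_accuracy=bal,
    )


def evaluate_predictions(pred, truth, granularity: str = "per-base",
                         threshold: float = 0.5) -> MetricsReport:
    """Evaluate aligned prediction/truth collections at a given granularity.

    * ``per-base``: flat concatenation of per-position probabilities.
    * ``per-entry``: upper triangles of score matrices, binarized.
    * ``per-pair``: pair sets of PairTables (precision/recall style counts;
      true negatives are the remaining upper-triangle entries).
    """
    if granularity in ("per-base", "per-entry"):
        ps, ts = [], []
        for p, t in zip(pred, truth, strict=True):
            p = np.asarray(p, dtype=float)
            t = np.asarray(t, dtype=float)
            if granularity == "per-entry":
                iu = np.triu_indices(p.shape[0], k=1)
                p, t = p[iu], t[iu]
            ps.append(p.ravel())
            ts.append(t.ravel())
        return binary_report(
            np.concatenate(ps), np.concatenate(ts), threshold, granularity
        )
    if granularity != "per-pair":
        raise ValueError(f"unknown granularity {granularity!r}")
    tp = fp = fn = tn = 0
    for ppt, tpt in zip(pred, truth, strict=True):
        a, b = set(ppt.pairs()), set(tpt.pairs())
        tp += len(a & b)
        fp += len(a - b)
        fn += len(b - a)
        tn += ppt.n * (ppt.n - 1) // 2 - len(a | b)
    n = tp + fp + tn + fn
    return MetricsReport(
        accuracy=(tp + tn) / n if n else 0.0,
        f1=f1_score(tp, fp, fn),
        loss=float("nan"),
        mcc=mcc(tp, fp, tn, fn),
        granularity="per-pair",
    )
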