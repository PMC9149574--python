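"""Confusion-matrix metrics, ROC curve and AUC.

Metrics are computed on [0, 1]; reports format them as percentages.
GMean is the geometric mean sqrt(SEN * SPE), a balanced summary robust to
class imbalance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from ._errors import InputError, UndefinedMetricError

__all__ = ["ConfusionCounts", "MetricSet", "confusion", "compute_metrics", "roc_auc"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    """acc, sen, spe, gmean, f1 in [0,1]; auc present when scores were given."""

    acc: float
    sen: float
    spe: float
    gmean: float
    f1: float
    auc: float | None = None

    def as_percent_dict(self) -> dict[str, float]:
        d = {
            "ACC": 100.0 * self.acc,
            "SEN": 100.0 * self.sen,
            "SPE": 100.0 * self.spe,
            "GMean": 100.0 * self.gmean,
            "F1": 100.0 * self.f1,
        }
        if self.auc is not None:
            d["AUC"] = self.auc
        return d


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Count TP/TN/FP/FN with label 1 positive."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise InputError(f"length mismatch: {yt.shape} vs {yp.shape}")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise InputError("labels must be binary 0/1")
    yt = yt.astype(int)
    yp = yp.astype(int)
    return ConfusionCounts(
        TP=int(np.sum((yt == 1) & (yp == 1))),
        TN=int(np.sum((yt == 0) & (yp == 0))),
        FP=int(np.sum((yt == 0) & (yp == 1))),
        FN=int(np.sum((yt == 1) & (yp == 0))),
    )


def compute_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricSet:
    """ACC, SEN, SPE, GMean = sqrt(SEN*SPE), F1 from one confusion table."""
    if min(counts.TP, counts.TN, counts.FP, counts.FN) < 0:
        raise InputError("confusion counts must be non-negative")
    if counts.total == 0:
        raise InputError("empty confusion table")
    if counts.TP + counts.FN == 0:
        raise UndefinedMetricError("SEN undefined: no positive samples (TP+FN = 0)")
    if counts.TN + counts.FP == 0:
        raise UndefinedMetricError("SPE undefined: no negative samples (TN+FP = 0)")
    acc = (counts.TP + counts.TN) / counts.total
    sen = counts.TP / (counts.TP + counts.FN)
    spe = counts.TN / (counts.TN + counts.FP)
    gmean = float(np.sqrt(sen * spe))
    f1_den = 2 * counts.TP + counts.FP + counts.FN
    if f1_den == 0:
        warnings.warn("F1 denominator is zero (no positives anywhere); F1 set to 0")
        f1 = 0.0
    else:
        f1 = 2 * counts.TP / f1_den
    return MetricSet(acc=acc, sen=sen, spe=spe, gmean=gmean, f1=f1, auc=auc)


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) over all score thresholds, and trapezoidal AUC.

    Tied scores are grouped into one threshold; the curve always contains
    the endpoints (0,0) and (1,1).  The trapezoidal area equals the
    Mann-Whitney U statistic normalised by n_pos * n_neg.
    """
    yt = np.asarray(y_true).astype(int)
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape:
        raise InputError(f"length mismatch: {yt.shape} vs {s.shape}")
    if len(np.unique(yt)) < 2:
        raise InputError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(yt, s, drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(_trapezoid_auc(fpr, tpr))
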