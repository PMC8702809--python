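"""Class-weighted cross-entropy, the scheduled deep-supervision loss, and
pixel-classification metrics (Acc/Se/Sp, ROC, AUC).

Vessel pixels are a small minority of a fundus image, so the binary
cross-entropy is weighted by the class balance of the target itself:
with m pixels, X+ vessel and X- background pixels, the vessel term is
weighted by alpha = X-/m and the background term by 1 - alpha = X+/m,

    Loss = -(1/m) * sum_i [ alpha * y_i * log(yhat_i)
                            + (1 - alpha) * (1 - y_i) * log(1 - yhat_i) ].

During training four such losses are combined — three from the deep
supervision heads and one from the main output — with a weight
beta = 1 - epoch/total_epochs on the supervision terms, so the auxiliary
heads guide early training and fade out by the final epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn import metrics as _skm

from .errors import DataError, ParameterError, ShapeError, UndefinedMetricError

EPS = 1e-7


@dataclass
class ClassBalance:
    """Pixel class balance of a batch target: alpha = X-/m weights vessels."""

    m: int
    x_plus: int
    x_minus: int

    def __post_init__(self) -> None:
        if self.x_plus + self.x_minus != self.m:
            raise ParameterError("x_plus + x_minus must equal m")

    @property
    def alpha(self) -> float:
        return self.x_minus / self.m

    @classmethod
    def from_target(cls, y: np.ndarray) -> "ClassBalance":
        y = np.asarray(y)
        m = int(y.size)
        xp = int((y > 0).sum())
        return cls(m=m, x_plus=xp, x_minus=m - xp)


@dataclass
class LossSchedule:
    """beta = 1 - epoch/total_epochs; 1 at the first epoch, 0 at the last."""

    epoch: int
    total_epochs: int = 500

    def __post_init__(self) -> None:
        if not 0 <= self.epoch <= self.total_epochs:
            raise ParameterError("epoch must lie in [0, total_epochs]")

    @property
    def beta(self) -> float:
        return 1.0 - self.epoch / self.total_epochs


def beta_weight(sched: LossSchedule) -> float:
    return sched.beta


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def weighted_bce(
    y: np.ndarray, yhat: np.ndarray, balance: Optional[ClassBalance] = None
) -> float:
    """Class-weighted binary cross-entropy (natural log, mean over pixels).

    Predictions are clamped to [EPS, 1-EPS] before the logs; the balance is
    computed from the target when not supplied.
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ShapeError(f"target {y.shape} vs prediction {yhat.shape}")
    if balance is None:
        balance = ClassBalance.from_target(y)
    a = balance.alpha
    p = np.clip(yhat, EPS, 1.0 - EPS)
    ll = a * y * np.log(p) + (1.0 - a) * (1.0 - y) * np.log(1.0 - p)
    return float(-ll.mean())


def total_loss(
    l1: float, l2: float, l3: float, l4: float, beta: float, beta_all: bool = False
) -> float:
    """Combine supervision losses l1..l3 and the main loss l4.

    Default: beta*(l1+l2+l3) + l4, so the main loss never vanishes at the
    final epoch; beta_all applies beta to all four terms instead.
    """
    for v in (l1, l2, l3, l4):
        if v < 0:
            raise ParameterError("loss components must be non-negative")
    if beta_all:
        return beta * (l1 + l2 + l3 + l4)
    return beta * (l1 + l2 + l3) + l4


def confusion(
    pred: np.ndarray, truth: np.ndarray, mask: Optional[np.ndarray] = None
) -> ConfusionCounts:
    """Pixel confusion counts restricted to mask==1 (whole image if None)."""
    pred = np.asarray(pred) > 0
    truth = np.asarray(truth) > 0
    if pred.shape != truth.shape:
        raise ShapeError("pred and truth shapes differ")
    if mask is None:
        mask = np.ones(pred.shape, dtype=bool)
    else:
        mask = np.asarray(mask) > 0
        if mask.shape != pred.shape:
            raise ShapeError("mask shape differs")
    if not mask.any():
        raise DataError("empty evaluation mask")
    p = pred[mask]
    t = truth[mask]
    tp = int(np.sum(p & t))
    tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def acc_se_sp(
    c: ConfusionCounts,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """Accuracy, sensitivity, specificity; None where the denominator is zero."""
    if c.total == 0:
        raise UndefinedMetricError("no evaluated pixels")
    acc = (c.tp + c.tn) / c.total
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) > 0 else None
    return acc, se, sp


def roc_auc(
    scores: np.ndarray, truth: np.ndarray, mask: Optional[np.ndarray] = None
) -> tuple[np.ndarray, float]:
    """ROC curve (FPR, TPR columns) and trapezoidal AUC within the mask.

    The curve sweeps every distinct score threshold; the AUC equals the
    pairwise-concordance statistic with ties counted as one half.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth) > 0
    if scores.shape != truth.shape:
        raise ShapeError("scores and truth shapes differ")
    if mask is not None:
        mask = np.asarray(mask) > 0
        if mask.shape != scores.shape:
            raise ShapeError("mask shape differs")
        scores = scores[mask]
        truth = truth[mask]
    else:
        scores = scores.ravel()
        truth = truth.ravel()
    if truth.all() or not truth.any():
        raise UndefinedMetricError("ROC needs both classes in the truth")
    fpr, tpr, _ = _skm.roc_curve(truth.astype(int), scores, drop_intermediate=False)
    auc = float(_skm.auc(fpr, tpr))
    return np.column_stack([fpr, tpr]), auc
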