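"""Regression and threshold-classification metrics for solubility prediction.

Continuous predictions are scored with RMSE and the coefficient of
determination R^2.  For comparison with binary solubility predictors, both
the true and the predicted values are additionally binarized at 0.5 —
a protein strictly below the threshold is insoluble, otherwise soluble
(so a prediction of exactly 0.5 counts as soluble) — and scored with
accuracy, precision, recall, F1 and AUC.  AUC is computed from the
continuous predictions against the binarized truth via the rank
(Mann-Whitney) statistic with mid-ranks for ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .exceptions import ShapeError

#: Solubility threshold separating insoluble (< 0.5) from soluble (>= 0.5).
SOLUBILITY_THRESHOLD = 0.5


def _check_pair(y: np.ndarray, y_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape:
        raise ShapeError(f"length mismatch: y has {y.size}, y_hat has {y_hat.size}")
    if y.size == 0:
        raise ShapeError("metrics require at least one observation")
    return y, y_hat


def rmse(y, y_hat) -> float:
    """Root-mean-square error, the training loss and primary regression metric."""
    y, y_hat = _check_pair(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def r2(y, y_hat) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``.

    Requires at least two observations and non-constant ``y``.
    """
    y, y_hat = _check_pair(y, y_hat)
    if y.size < 2:
        raise ShapeError("R^2 requires at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ShapeError("R^2 undefined for constant y (zero variance)")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def binarize(values, threshold: float = SOLUBILITY_THRESHOLD) -> np.ndarray:
    """Soluble (1) iff value >= threshold; insoluble (0) strictly below."""
    return (np.asarray(values, dtype=float) >= threshold).astype(int)


def roc_auc(y_true_binary, scores) -> float:
    """Rank-statistic AUC: P(score_pos > score_neg) with ties counted half.

    Returns ``nan`` when only one class is present.
    """
    y = np.asarray(y_true_binary, dtype=int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)  # mid-ranks for ties
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class MetricRecord:
    """The full evaluation record for one set of predictions.

    ``auc`` is ``nan`` (with ``auc_defined=False``) when the binarized truth
    contains a single class; ``f1`` is 0 by convention when precision and
    recall are both zero.
    """

    rmse: float
    r2: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float
    auc_defined: bool = True
    confusion: dict = field(default_factory=dict)

    NUMERIC_FIELDS = ("rmse", "r2", "accuracy", "precision", "recall", "f1", "auc")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.NUMERIC_FIELDS}


def classify_metrics(y, y_hat, threshold: float = SOLUBILITY_THRESHOLD) -> dict:
    """Threshold-classification metrics from continuous values.

    Both truth and prediction are binarized at ``threshold`` (>= threshold is
    soluble, the positive class).  Returns a dict with the confusion counts,
    accuracy, precision, recall, F1, AUC and an ``auc_defined`` flag.
    """
    y, y_hat = _check_pair(y, y_hat)
    yb = binarize(y, threshold)
    pb = binarize(y_hat, threshold)
    tp = int(np.sum((yb == 1) & (pb == 1)))
    fp = int(np.sum((yb == 0) & (pb == 1)))
    fn = int(np.sum((yb == 1) & (pb == 0)))
    tn = int(np.sum((yb == 0) & (pb == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    auc = roc_auc(yb, y_hat)
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
        "accuracy": (tp + tn) / y.size,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "auc": auc,
        "auc_defined": not math.isnan(auc),
    }


def evaluate_predictions(y, y_hat, threshold: float = SOLUBILITY_THRESHOLD) -> MetricRecord:
    """Compute the complete regression + classification metric record."""
    cls = classify_metrics(y, y_hat, threshold)
    return MetricRecord(
        rmse=rmse(y, y_hat),
        r2=r2(y, y_hat),
        accuracy=cls["accuracy"],
        precision=cls["precision"],
        recall=cls["recall"],
        f1=cls["f1"],
        auc=cls["auc"],
        auc_defined=cls["auc_defined"],
        confusion={k: cls[k] for k in ("tp", "fp", "fn", "tn")},
    )
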