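"""Losses, Mixup, classification metrics, ROC/AUC and evaluation
aggregation.

The focal loss is computed from logits in log-sum-exp form, so p_t = 0 never
reaches the logarithm.  Metrics follow the standard confusion-matrix
definitions with undefined ratios reported as NaN and flagged rather than
coerced to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn.autodiff import Tensor, as_tensor
from .nn.ops import log_softmax

__all__ = [
    "focal_loss",
    "cross_entropy",
    "mixup",
    "MetricsReport",
    "compute_metrics",
    "confusion_counts",
    "RocCurve",
    "roc_auc",
    "fit_with_manifest",
    "evaluate",
    "subject_aggregate",
]


def _as_soft_labels(labels, n_classes: int = 2) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.ndim == 1:
        onehot = np.zeros((labels.size, n_classes))
        onehot[np.arange(labels.size), labels.astype(int)] = 1.0
        return onehot
    return labels.astype(float)


def focal_loss(logits, labels, alpha: float = 0.25, gamma: float = 2.0) -> Tensor:
    """Mean focal loss -alpha (1 - p_t)^gamma log p_t over the batch.

    ``labels`` may be integer class indices or soft (e.g. Mixup) label rows;
    with gamma=0 and alpha=1 this is exactly the cross-entropy.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    logits = as_tensor(logits)
    if logits.ndim == 1:
        logits = logits.reshape(1, -1)
    y = _as_soft_labels(labels, logits.shape[-1])
    logp = log_softmax(logits, axis=-1)
    p = logp.exp()
    per_class = (1.0 - p) ** gamma * logp * (-alpha)
    return (Tensor(y) * per_class).sum(axis=-1).mean()


def cross_entropy(logits, labels) -> Tensor:
    """Softmax cross-entropy; the gamma=0, alpha=1 case of the focal loss."""
    return focal_loss(logits, labels, alpha=1.0, gamma=0.0)


def mixup(batch_x: np.ndarray, batch_y, rng: np.random.Generator,
          alpha: float = 0.2, lam: float | None = None):
    """Convex combination of a batch with a seeded permutation of itself.

    ``lam`` is drawn Beta(alpha, alpha) per batch unless given.  Labels are
    mixed as one-hot rows, so they always sum to 1.  A batch of one is
    returned unchanged.
    """
    x = np.asarray(batch_x, float)
    y = _as_soft_labels(batch_y)
    if lam is None:
        lam = float(rng.beta(alpha, alpha))
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lam must lie in [0, 1]")
    if x.shape[0] < 2:
        return x, y, 1.0
    j = rng.permutation(x.shape[0])
    x_mixed = lam * x + (1 - lam) * x[j]
    y_mixed = lam * y + (1 - lam) * y[j]
    return x_mixed, y_mixed, lam


@dataclass
class MetricsReport:
    """Confusion counts and derived rates; undefined ratios are NaN with the
    offending metric named in ``undefined``."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float = field(init=False)
    precision: float = field(init=False)
    recall: float = field(init=False)
    specificity: float = field(init=False)
    f1: float = field(init=False)
    undefined: list[str] = field(init=False, default_factory=list)

    def __post_init__(self) -> None:
        tp, fp, fn, tn = self.tp, self.fp, self.fn, self.tn
        if min(tp, fp, fn, tn) < 0 or tp + fp + fn + tn == 0:
            raise ValueError("confusion counts must be non-negative, not all 0")

        def ratio(num, den, name):
            if den == 0:
                self.undefined.append(name)
                return float("nan")
            return num / den

        self.undefined = []
        self.accuracy = (tp + tn) / (tp + fp + fn + tn)
        self.precision = ratio(tp, tp + fp, "precision")
        self.recall = ratio(tp, tp + fn, "recall")
        self.specificity = ratio(tn, tn + fp, "specificity")
        if np.isnan(self.precision) or np.isnan(self.recall) \
                or self.precision + self.recall == 0:
            self.undefined.append("f1")
            self.f1 = float("nan")
        else:
            self.f1 = 2 * self.precision * self.recall / (
                self.precision + self.recall
            )


def confusion_counts(y_true, y_pred, positive=1) -> tuple[int, int, int, int]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_pred == positive) & (y_true == positive)))
    fp = int(np.sum((y_pred == positive) & (y_true != positive)))
    fn = int(np.sum((y_pred != positive) & (y_true == positive)))
    tn = int(np.sum((y_pred != positive) & (y_true != positive)))
    return tp, fp, fn, tn


def compute_metrics(tp: int, fp: int, fn: int, tn: int) -> MetricsReport:
    """Metrics from confusion counts (accuracy, precision, recall,
    specificity, F1)."""
    return MetricsReport(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(scores, labels, positive=1) -> RocCurve:
    """ROC curve by threshold sweep over the unique scores; AUC by the
    trapezoid rule (ties contribute one half)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = labels == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    tpr = np.empty(thresholds.size)
    fpr = np.empty(thresholds.size)
    for i, thr in enumerate(thresholds):
        calls = scores >= thr
        tpr[i] = np.sum(calls & pos) / n_pos
        fpr[i] = np.sum(calls & ~pos) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def fit_with_manifest(estimator, X, y, manifest: pd.DataFrame):
    """Fit on the manifest's train rows after checking for subject leakage.

    ``manifest`` has one row per sample of X with columns ``subject_id`` and
    ``split``; training refuses to start if any subject appears in both
    splits.
    """
    train_subj = set(manifest.loc[manifest["split"] == "train", "subject_id"])
    test_subj = set(manifest.loc[manifest["split"] == "test", "subject_id"])
    leaked = train_subj & test_subj
    if leaked:
        raise ValueError(f"subject leakage across splits: {sorted(leaked)}")
    rows = np.flatnonzero((manifest["split"] == "train").to_numpy())
    X_train = X[rows] if not isinstance(X, tuple) else tuple(x[rows] for x in X)
    estimator.fit(X_train, np.asarray(y)[rows])
    return estimator


def subject_aggregate(proba: np.ndarray, subject_ids) -> tuple[np.ndarray, np.ndarray]:
    """Mean predicted probability per subject (rows align with the returned
    subject array, sorted by first appearance)."""
    subject_ids = np.asarray(subject_ids)
    order = pd.unique(subject_ids)
    agg = np.stack([proba[subject_ids == s].mean(axis=0) for s in order])
    return order, agg


def evaluate(estimator, X, y, subject_ids=None, positive_class=None) -> dict:
    """Slice-level metrics, plus subject-level metrics by mean-probability
    aggregation when subject ids are supplied.

    Returns {"slice": MetricsReport, "slice_auc": float, and, if subject ids
    are given, "subject": MetricsReport, "subject_auc": float}.
    """
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty evaluation manifest")
    proba = estimator.predict_proba(X)
    classes = list(estimator.classes_)
    pos = classes[-1] if positive_class is None else positive_class
    pos_col = classes.index(pos)
    y_pred = np.asarray(classes, dtype=y.dtype)[np.argmax(proba, axis=1)]
    out: dict = {}
    tp, fp, fn, tn = confusion_counts(y == pos, y_pred == pos, positive=True)
    out["slice"] = compute_metrics(tp, fp, fn, tn)
    if len(set(y)) > 1:
        out["slice_auc"] = roc_auc(proba[:, pos_col], y == pos, positive=True).auc
    if subject_ids is not None:
        subjects, agg = subject_aggregate(proba, subject_ids)
        subj_y = np.asarray(
            [y[np.asarray(subject_ids) == s][0] for s in subjects]
        )
        subj_pred = np.asarray(classes, dtype=y.dtype)[np.argmax(agg, axis=1)]
        tp, fp, fn, tn = confusion_counts(subj_y == pos, subj_pred == pos,
                                          positive=True)
        out["subject"] = compute_metrics(tp, fp, fn, tn)
        if len(set(subj_y)) > 1:
            out["subject_auc"] = roc_auc(agg[:, pos_col], subj_y == pos,
                                         positive=True).auc
    return out
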