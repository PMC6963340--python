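"""Binary-classification metrics and leakage-safe stratified cross-validation.

Six statistics are reported per decision point: accuracy, sensitivity and
specificity (percent), F-measure (in [0, 1]), Matthews correlation
coefficient (in [−1, 1]) and ROC area (percent). Fold results are
aggregated by pooling confusion counts, matching "correct / total"
overall-accuracy arithmetic; per-fold metrics are kept alongside.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

REPORT_COLUMNS = ["Accuracy", "Sensitivity", "Specificity", "F-Measure", "MCC", "ROC Area"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"negative count {name}={v}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass
class NodeMetrics:
    accuracy: float       # percent
    sensitivity: float    # percent
    specificity: float    # percent
    f_measure: float      # [0, 1]
    mcc: float            # [-1, 1]
    roc_area: float | None  # percent, absent without decision scores

    def as_report_row(self) -> dict:
        return {
            "Accuracy": self.accuracy,
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "F-Measure": self.f_measure,
            "MCC": self.mcc,
            "ROC Area": self.roc_area,
        }


def confusion(y_true, y_pred) -> ConfusionCounts:
    """Standard binary confusion counts with class 1 as positive."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def roc_area(y_true, scores) -> float:
    """Area under the ROC curve, in percent, from continuous scores.

    Equivalent to trapezoidal integration with midpoint rank handling of
    tied scores (the Mann–Whitney identity).
    """
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores length mismatch")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC area needs at least one positive and one negative")
    ranks = rankdata(scores, method="average")
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return 100.0 * auc


def metrics_from_confusion(
    c: ConfusionCounts, y_true=None, scores_for_roc=None
) -> NodeMetrics:
    """The six per-node statistics; zero-denominator cases yield 0, and the
    ROC area is reported absent (None) when no decision scores are given."""
    n = c.n
    if n == 0:
        raise ValueError("empty confusion table")
    acc = 100.0 * (c.tp + c.tn) / n
    sens = 100.0 * c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    spec = 100.0 * c.tn / (c.tn + c.fp) if (c.tn + c.fp) else 0.0
    prec = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    sens01 = sens / 100.0
    f = 2.0 * prec * sens01 / (prec + sens01) if (prec + sens01) else 0.0
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else 0.0
    auc = None
    if scores_for_roc is not None:
        if y_true is None:
            raise ValueError("ROC area requires y_true alongside the scores")
        auc = roc_area(y_true, scores_for_roc)
    return NodeMetrics(
        accuracy=acc, sensitivity=sens, specificity=spec,
        f_measure=f, mcc=mcc, roc_area=auc,
    )


def overall_accuracy(n_correct: int, n_total: int) -> float:
    """Percent of correctly classified samples, 100·correct/total."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_correct <= n_total):
        raise ValueError(f"n_correct={n_correct} outside [0, {n_total}]")
    return 100.0 * n_correct / n_total


@dataclass
class CVResult:
    pooled: NodeMetrics
    pooled_counts: ConfusionCounts
    fold_metrics: list[NodeMetrics]
    fold_indices: list[tuple[np.ndarray, np.ndarray]]
    mean_of_folds: NodeMetrics | None = None


def stratified_folds(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified (train, test) index pairs; k is reduced with a warning
    when the rarest class has fewer than k members."""
    y = np.asarray(y)
    if k < 2:
        raise ValueError("cross-validation needs k >= 2")
    min_class = int(np.unique(y, return_counts=True)[1].min())
    if min_class < k:
        warnings.warn(
            f"rarest class has {min_class} samples; reducing folds from {k} to {max(2, min_class)}",
            stacklevel=2,
        )
        k = max(2, min_class)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(len(y)), y)]


def stratified_cv_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    pipeline: Callable[[np.ndarray, np.ndarray], object],
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Evaluate a train-only pipeline under stratified k-fold CV.

    ``pipeline(X_train, y_train)`` must return a fitted object exposing
    ``predict(X)`` and (optionally) ``decision_scores(X)``. Any resampling
    or feature selection belongs inside the pipeline, so evaluation folds
    stay untouched. Aggregation pools confusion counts across folds.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = stratified_folds(y, k, seed)
    pooled = ConfusionCounts(0, 0, 0, 0)
    fold_metrics: list[NodeMetrics] = []
    all_true: list[np.ndarray] = []
    all_scores: list[np.ndarray] = []
    for tr, te in folds:
        model = pipeline(X[tr], y[tr])
        pred = np.asarray(model.predict(X[te]), dtype=int)
        counts = confusion(y[te], pred)
        pooled = pooled + counts
        scores = None
        if hasattr(model, "decision_scores"):
            scores = np.asarray(model.decision_scores(X[te]), dtype=float)
            all_true.append(y[te])
            all_scores.append(scores)
        try:
            fold_metrics.append(metrics_from_confusion(counts, y[te], scores))
        except ValueError:
            fold_metrics.append(metrics_from_confusion(counts))
    y_pooled = np.concatenate(all_true) if all_true else None
    s_pooled = np.concatenate(all_scores) if all_scores else None
    pooled_metrics = metrics_from_confusion(pooled, y_pooled, s_pooled)
    present = [m for m in fold_metrics if m.roc_area is not None]
    mean_of_folds = NodeMetrics(
        accuracy=float(np.mean([m.accuracy for m in fold_metrics])),
        sensitivity=float(np.mean([m.sensitivity for m in fold_metrics])),
        specificity=float(np.mean([m.specificity for m in fold_metrics])),
        f_measure=float(np.mean([m.f_measure for m in fold_metrics])),
        mcc=float(np.mean([m.mcc for m in fold_metrics])),
        roc_area=float(np.mean([m.roc_area for m in present])) if present else None,
    )
    return CVResult(
        pooled=pooled_metrics,
        pooled_counts=pooled,
        fold_metrics=fold_metrics,
        fold_indices=folds,
        mean_of_folds=mean_of_folds,
    )
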