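"""Random Forest training, cross-validation and evaluation metrics.

Threshold metrics from the confusion table:

    Spec = TN / (FP + TN)
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN))
    Prec = TP / (FP + TP)
    Sen  = TP / (TP + FN)
    Acc  = (TP + TN) / (TP + FP + TN + FN)

plus AUC (area under the ROC curve, trapezoid rule — equivalently the
probability that a random positive outscores a random negative, ties
counting one half) and AUPR (area under the precision-recall curve by the
step-wise rule, i.e. average precision, with no linear interpolation).
Threshold metrics use a 0.5 cut on the forest's positive-class probability.

Cross-validation is stratified k-fold with a recorded seed so every fold
contains both classes and fold membership is reproducible; the tree-count
sweep reuses one fold assignment across the whole grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (auc as _trapz_auc, average_precision_score,
                             precision_recall_curve, roc_curve)
from sklearn.model_selection import StratifiedKFold

from .pairs import PairFeatureMatrix

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "CVResult",
    "RFConfig",
    "compute_metrics",
    "roc_auc",
    "pr_aupr",
    "train_predict",
    "score_fold",
    "kfold_cv",
    "sweep_trees",
]

METRIC_NAMES = ("spec", "mcc", "prec", "sen", "acc", "auc", "aupr")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    spec: float
    mcc: float
    prec: float
    sen: float
    acc: float
    auc: float | None = None
    aupr: float | None = None
    roc_points: np.ndarray | None = None   # columns FPR, TPR
    pr_points: np.ndarray | None = None    # columns recall, precision

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in METRIC_NAMES}


@dataclass(frozen=True)
class RFConfig:
    """Random Forest settings.

    The mtry fraction (0.5) and leaf size (10) depart from the common
    sqrt/fully-grown defaults because the pair vectors concatenate a large
    block of auto-covariance dims with a smaller informative embedding
    block; see the methods note for the rationale.
    """

    n_trees: int = 300
    seed: int = 0
    max_features: str | int | float = 0.5
    min_samples_leaf: int = 10
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def make(self) -> RandomForestClassifier:
        return RandomForestClassifier(n_estimators=self.n_trees,
                                      max_features=self.max_features,
                                      min_samples_leaf=self.min_samples_leaf,
                                      random_state=self.seed,
                                      n_jobs=self.n_jobs)


@dataclass
class CVResult:
    folds: list[MetricsReport]
    fold_assignment: np.ndarray
    seed: int
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.mean:
            for name in METRIC_NAMES:
                vals = [getattr(f, name) for f in self.folds]
                if any(v is None for v in vals):
                    continue
                self.mean[name] = float(np.mean(vals))
                self.sd[name] = float(np.std(vals, ddof=0))


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Threshold metrics from a confusion table.

    MCC is defined as 0 when its denominator vanishes; precision is 0 (with
    a warning) when no pair is predicted positive.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = (float(counts.tp), float(counts.tn),
                      float(counts.fp), float(counts.fn))
    spec = tn / (fp + tn) if fp + tn > 0 else 0.0
    sen = tp / (tp + fn) if tp + fn > 0 else 0.0
    if tp + fp > 0:
        prec = tp / (fp + tp)
    else:
        warnings.warn("no predicted positives; precision set to 0",
                      stacklevel=2)
        prec = 0.0
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    acc = (tp + tn) / counts.total
    return MetricsReport(spec=spec, mcc=float(mcc), prec=prec, sen=sen, acc=acc)


def _check_scores(scores, labels, need_both=True):
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d and aligned")
    if need_both and len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return scores, labels


def roc_auc(scores: Sequence[float], labels: Sequence[int]
            ) -> tuple[float, np.ndarray]:
    """AUC and the ROC curve points (FPR, TPR), tied scores grouped."""
    scores, labels = _check_scores(scores, labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(_trapz_auc(fpr, tpr)), np.column_stack([fpr, tpr])


def pr_aupr(scores: Sequence[float], labels: Sequence[int]
            ) -> tuple[float, np.ndarray]:
    """AUPR by the step-wise (right-continuous) rule and the PR points."""
    scores, labels = _check_scores(scores, labels, need_both=False)
    if np.sum(labels) == 0:
        raise ValueError("no positive labels")
    precision, recall, _ = precision_recall_curve(labels, scores)
    aupr = float(average_precision_score(labels, scores))
    return aupr, np.column_stack([recall, precision])


def train_predict(X_train: np.ndarray, y_train: np.ndarray,
                  X_test: np.ndarray, rf: RFConfig) -> np.ndarray:
    """Fit a Random Forest and return positive-class probabilities."""
    if len(np.unique(y_train)) < 2:
        raise ValueError("training set must contain both classes")
    if X_train.shape[1] != X_test.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: train {X_train.shape[1]}, "
            f"test {X_test.shape[1]}")
    clf = rf.make()
    clf.fit(X_train, y_train)
    proba = clf.predict_proba(X_test)
    return proba[:, list(clf.classes_).index(1)]


def score_fold(scores: np.ndarray, y_true: np.ndarray,
               threshold: float = 0.5) -> MetricsReport:
    """All metrics for one fold from probabilities and true labels."""
    pred = (scores >= threshold).astype(int)
    counts = ConfusionCounts(tp=int(np.sum((pred == 1) & (y_true == 1))),
                             tn=int(np.sum((pred == 0) & (y_true == 0))),
                             fp=int(np.sum((pred == 1) & (y_true == 0))),
                             fn=int(np.sum((pred == 0) & (y_true == 1))))
    report = compute_metrics(counts)
    report.auc, report.roc_points = roc_auc(scores, y_true)
    report.aupr, report.pr_points = pr_aupr(scores, y_true)
    return report


def _fold_assignment(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    classes, class_counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("dataset must contain both classes")
    if k > class_counts.min():
        raise ValueError(f"k={k} exceeds the minority class count")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=np.int64)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[test_idx] = fold
    return assignment


def kfold_cv(matrix: PairFeatureMatrix, rf: RFConfig,
             k: int = 5, seed: int = 0,
             fold_assignment: np.ndarray | None = None) -> CVResult:
    """Stratified k-fold cross-validation of the Random Forest."""
    y = matrix.y
    if fold_assignment is None:
        fold_assignment = _fold_assignment(y, k, seed)
    folds = []
    for fold in range(k):
        test = fold_assignment == fold
        scores = train_predict(matrix.X[~test], y[~test], matrix.X[test], rf)
        folds.append(score_fold(scores, y[test]))
    return CVResult(folds=folds, fold_assignment=fold_assignment, seed=seed)


def sweep_trees(matrix: PairFeatureMatrix, rf: RFConfig,
                grid: Sequence[int] = tuple(range(180, 341, 20)),
                k: int = 5, seed: int = 0,
                early_stop: bool = False):
    """Accuracy of the forest over a tree-count grid with shared folds.

    Returns (table, fold_assignment) where table is a pandas DataFrame of
    per-fold accuracies, one row per fold and one column per tree count,
    with appended "mean" and "sd" rows.  With ``early_stop`` the grid is
    truncated as soon as the mean accuracy drops below the previous grid
    point's.
    """
    import pandas as pd

    if len(grid) == 0:
        raise ValueError("empty tree-count grid")
    assignment = _fold_assignment(matrix.y, k, seed)
    columns: dict[int, list[float]] = {}
    prev_mean = -np.inf
    for n_trees in grid:
        cv = kfold_cv(matrix, RFConfig(n_trees=n_trees, seed=rf.seed,
                                       max_features=rf.max_features,
                                       min_samples_leaf=rf.min_samples_leaf,
                                       n_jobs=rf.n_jobs),
                      k=k, seed=seed, fold_assignment=assignment)
        columns[n_trees] = [f.acc for f in cv.folds]
        mean = cv.mean["acc"]
        if early_stop and mean < prev_mean:
            break
        prev_mean = mean
    table = pd.DataFrame(columns, index=[f"fold{i}" for i in range(k)])
    table.loc["mean"] = table.iloc[:k].mean()
    table.loc["sd"] = table.iloc[:k].std(ddof=0)
    return table, assignment
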