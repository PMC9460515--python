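"""Capped decision-tree classifier and the evaluation metrics.

The classifier is a CART-style axis-aligned binary tree grown by Gini
impurity reduction with the split count capped at 100 (a binary tree with
``s`` splits has ``s + 1`` leaves, so the cap maps to ``max_leaf_nodes =
101``), no pruning.  Metrics are computed one-vs-rest from the confusion
matrix with the textbook formulas

    precision = TP / (TP + FP)        recall = TP / (TP + FN)
    F1 = 2 p r / (p + r)              accuracy = trace(C) / sum(C)

and reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = ["FineTreeClassifier", "ClassificationReport", "train_tree",
           "evaluate", "report_from_predictions"]


class FineTreeClassifier(ClassifierMixin, BaseEstimator):
    """Gini decision tree with a hard cap on the number of splits.

    A thin sklearn-compatible estimator so it drops into pipelines and
    model selection; ``max_splits=100`` reproduces the "fine tree" preset
    of common GUI toolboxes.
    """

    def __init__(self, max_splits: int = 100, min_samples_leaf: int = 1,
                 random_state: int | None = 0):
        self.max_splits = max_splits
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values")
        y = np.asarray(y)
        if np.unique(y).size < 2:
            raise ValueError("need at least 2 classes to fit")
        self.tree_ = DecisionTreeClassifier(
            criterion="gini",
            max_leaf_nodes=self.max_splits + 1,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
        ).fit(X, y)
        self.classes_ = self.tree_.classes_
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_")
        return self.tree_.predict(np.asarray(X, dtype=float))

    def predict_proba(self, X):
        check_is_fitted(self, "tree_")
        return self.tree_.predict_proba(np.asarray(X, dtype=float))


def train_tree(features, labels, max_splits: int = 100,
               min_samples_leaf: int = 1, seed: int = 0) -> FineTreeClassifier:
    """Fit a capped CART tree; deterministic under a fixed seed."""
    return FineTreeClassifier(max_splits=max_splits,
                              min_samples_leaf=min_samples_leaf,
                              random_state=seed).fit(features, labels)


@dataclass
class ClassificationReport:
    """Confusion matrix (rows = true, cols = predicted) plus one-vs-rest
    per-class metrics and overall accuracy, all in percent."""

    classes: np.ndarray
    confusion: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float
    absent_classes: list = field(default_factory=list)

    def per_class(self, cls) -> dict[str, float]:
        i = int(np.flatnonzero(self.classes == cls)[0])
        return {"precision": float(self.precision[i]),
                "recall": float(self.recall[i]),
                "f1": float(self.f1[i])}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "p": self.precision, "r": self.recall, "F1": self.f1,
        }, index=[f"class_{c}" for c in self.classes])
        df.loc["accuracy"] = [self.accuracy, np.nan, np.nan]
        return df

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_frame().to_string(float_format=lambda v: f"{v:.2f}")


def report_from_predictions(y_true, y_pred, classes=None) -> ClassificationReport:
    """Build the report from label vectors via the confusion matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty test set")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    conf = _sk_confusion(y_true, y_pred, labels=classes)
    total = conf.sum()
    tp = np.diag(conf).astype(float)
    fp = conf.sum(axis=0) - tp
    fn = conf.sum(axis=1) - tp
    absent = [c for c, row in zip(classes, conf.sum(axis=1)) if row == 0]

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        r = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(p + r > 0, 2 * p * r / (p + r), 0.0)
    accuracy = float(tp.sum() / total) if total else 0.0
    return ClassificationReport(
        classes=classes, confusion=conf,
        precision=100 * p, recall=100 * r, f1=100 * f1,
        accuracy=100 * accuracy, absent_classes=absent)


def evaluate(model, test_features, test_labels) -> ClassificationReport:
    """Predict on the test split and compute the report.

    Classes absent from the test set get zero metrics and are listed in
    ``absent_classes``.
    """
    pred = model.predict(test_features)
    classes = np.asarray(getattr(model, "classes_", np.unique(test_labels)))
    return report_from_predictions(test_labels, pred, classes)
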