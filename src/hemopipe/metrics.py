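"""Stratified splitting, outer classifiers, and macro-averaged evaluation.

The evaluation convention follows clinical multi-class reporting on
confusion matrices (rows = true class, columns = predicted class):

* per-class TPR (recall, sensitivity) = diagonal / row sum, and
  FNR = 1 - TPR;
* per-class precision = diagonal / column sum;
* per-class "accuracy" is reported as the class TPR;
* overall accuracy = trace / total;
* macro metrics are unweighted means of the per-class values, with
  F1_c = 2 * precision_c * recall_c / (precision_c + recall_c).

The train/test split is stratified with a floor rule: each class
contributes floor(fraction * n_c) training rows, the remainder testing.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "SplitPlan",
    "ConfusionMatrix",
    "EvaluationReport",
    "CLASSIFIER_PRESETS",
    "stratified_split",
    "confusion",
    "class_rates",
    "macro_metrics",
    "make_classifier",
    "train_eval",
]


@dataclass(frozen=True)
class SplitPlan:
    """Row indices of a stratified train/test partition."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    fraction: float


def stratified_split(labels, fraction: float = 0.7, seed: int | np.random.Generator = 0) -> SplitPlan:
    """Stratified split with per-class train count floor(fraction * n_c).

    Sizes are deterministic given the class sizes; only the membership is
    randomized by the seed.
    """
    if not 0 < fraction < 1:
        raise ValueError("train fraction must be in (0, 1)")
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("no labels to split")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            raise ValueError(f"class {cls!r} is empty")
        n_train = int(np.floor(fraction * idx.size))
        perm = rng.permutation(idx)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return SplitPlan(
        train_idx=np.sort(np.concatenate(train)),
        test_idx=np.sort(np.concatenate(test)),
        fraction=fraction,
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    classes: tuple

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.classes):
            raise ValueError("confusion matrix must be K x K with K class labels")
        if (c < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())


def confusion(y_true, y_pred, classes=None) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a confusion matrix."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label vectors must have equal length")
    if classes is None:
        classes = tuple(np.unique(np.concatenate([y_true, y_pred])))
    else:
        classes = tuple(classes)
        known = set(classes)
        stray = set(np.unique(np.concatenate([y_true, y_pred]))) - known
        if stray:
            raise ValueError(f"labels {sorted(map(str, stray))} not in class order {classes}")
    counts = _sk_confusion(y_true, y_pred, labels=list(classes))
    return ConfusionMatrix(counts=counts, classes=classes)


def class_rates(cm: ConfusionMatrix) -> dict[str, np.ndarray]:
    """Per-class TPR, FNR, precision, recall and accuracy from a matrix.

    Per-class accuracy follows the TPR convention.  A class never predicted
    has undefined precision; it is reported as 0 with a warning.
    """
    counts = np.asarray(cm.counts, dtype=float)
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if (row <= 0).any():
        raise ValueError("every true class must have at least one test sample")
    diag = np.diag(counts)
    tpr = diag / row
    if (col == 0).any():
        warnings.warn("a class was never predicted; its precision is reported as 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, diag / np.maximum(col, 1e-300), 0.0)
    return {
        "tpr": tpr,
        "fnr": 1.0 - tpr,
        "precision": precision,
        "recall": tpr,
        "accuracy": tpr,
    }


@dataclass
class EvaluationReport:
    """Per-class and macro-averaged evaluation of one classifier run."""

    confusion: ConfusionMatrix
    per_class: dict[str, np.ndarray]
    overall_accuracy: float
    macro_sensitivity: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    selected_features: int | None = None
    total_features: int | None = None
    classifier: str = ""

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "classes": [str(c) for c in self.confusion.classes],
            "confusion": np.asarray(self.confusion.counts).tolist(),
            "per_class": {k: list(map(float, v)) for k, v in self.per_class.items()},
            "overall_accuracy": self.overall_accuracy,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "selected_features": self.selected_features,
            "total_features": self.total_features,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def macro_metrics(cm: ConfusionMatrix) -> EvaluationReport:
    """Overall accuracy plus unweighted macro averages of class metrics."""
    rates = class_rates(cm)
    counts = np.asarray(cm.counts, dtype=float)
    prec, rec = rates["precision"], rates["recall"]
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(prec + rec > 0, 2 * prec * rec / np.maximum(prec + rec, 1e-300), 0.0)
    return EvaluationReport(
        confusion=cm,
        per_class={**rates, "f1": f1},
        overall_accuracy=float(np.trace(counts) / counts.sum()),
        macro_sensitivity=float(rates["tpr"].mean()),
        macro_precision=float(prec.mean()),
        macro_recall=float(rec.mean()),
        macro_f1=float(f1.mean()),
    )


def _knn(k: int, metric: str = "euclidean", **kw):
    return KNeighborsClassifier(n_neighbors=k, metric=metric, algorithm="brute", **kw)


#: MATLAB-style preset names -> factory(seed, n_train) for the outer classifiers.
CLASSIFIER_PRESETS = {
    "knn-fine": lambda seed, n: _knn(1),
    "knn-cosine": lambda seed, n: _knn(min(10, max(1, n)), metric="cosine"),
    "knn-cubic": lambda seed, n: _knn(min(10, max(1, n)), metric="minkowski", p=3),
    "knn-coarse": lambda seed, n: _knn(min(100, max(1, n))),
    "svm-gaussian": lambda seed, n: make_pipeline(
        StandardScaler(), SVC(kernel="rbf", random_state=seed)),
    "svm-quadratic": lambda seed, n: make_pipeline(
        StandardScaler(), SVC(kernel="poly", degree=2, random_state=seed)),
    "svm-regression": lambda seed, n: make_pipeline(
        StandardScaler(), SVC(kernel="linear", random_state=seed)),
    "tree-medium": lambda seed, n: DecisionTreeClassifier(max_leaf_nodes=20, random_state=seed),
    "nn-wide": lambda seed, n: make_pipeline(
        StandardScaler(),
        MLPClassifier(hidden_layer_sizes=(100,), max_iter=500, random_state=seed),
    ),
}


def make_classifier(spec: str, seed: int = 0, n_train: int | None = None):
    """Instantiate an outer classifier from its preset name."""
    if spec not in CLASSIFIER_PRESETS:
        raise ValueError(
            f"unknown classifier {spec!r}; choose from {sorted(CLASSIFIER_PRESETS)}"
        )
    return CLASSIFIER_PRESETS[spec](seed, n_train if n_train is not None else 10**9)


def train_eval(
    features: np.ndarray,
    labels,
    split: SplitPlan,
    spec: str = "knn-cosine",
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> EvaluationReport:
    """Fit one preset classifier on the train rows and evaluate the test rows.

    ``mask`` restricts the columns to a selection (0/1 or boolean vector);
    the report records how many of the available features were used.
    """
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    total = x.shape[1]
    if mask is not None:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != (total,):
            raise ValueError("mask length does not match feature count")
        if not mask.any():
            raise ValueError("selection mask is empty")
        x = x[:, mask]
    clf = make_classifier(spec, seed=seed, n_train=len(split.train_idx))
    clf.fit(x[split.train_idx], y[split.train_idx])
    pred = clf.predict(x[split.test_idx])
    cm = confusion(y[split.test_idx], pred, classes=tuple(np.unique(y)))
    report = macro_metrics(cm)
    report.selected_features = int(x.shape[1])
    report.total_features = int(total)
    report.classifier = spec
    return report
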