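"""Classifier backends and evaluation metrics.

Three classical backends sit behind one interface: linear discriminant
analysis (``"lda"``), a linear-kernel support vector machine (``"svm"``,
C = 1), and k-nearest neighbors (``"knn"``, k = 5, Euclidean). All are
deterministic at these defaults, which matters because classification
accuracy is the optimizer's fitness function.

Agreement beyond chance is measured by Cohen's kappa,
``(Acc - p_e) / (1 - p_e)``. The chance level ``p_e`` defaults to
``1/n_classes`` (0.25 for four balanced imagery classes); the
marginal-product estimate computed from the label distributions is
available behind ``chance="marginal"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .exceptions import ConfigurationError

__all__ = [
    "Classifier",
    "ConfusionCounts",
    "Metrics",
    "fit_classifier",
    "predict",
    "confusion",
    "accuracy",
    "cohen_kappa",
    "chance_level",
    "summarize",
]

CLASSIFIER_KINDS = ("lda", "svm", "knn")


@dataclass
class Classifier:
    """A fitted classification backend.

    ``estimator`` is the underlying scikit-learn model, or ``None`` for the
    degenerate case of featureless training data, where predictions fall
    back to the majority class (ties broken toward the lowest label).
    """

    kind: str
    estimator: object | None
    classes: np.ndarray
    n_features: int
    fallback_label: int | None = None


def _make_estimator(kind: str):
    if kind == "lda":
        return LinearDiscriminantAnalysis()
    if kind == "svm":
        return SVC(kernel="linear", C=1.0)
    if kind == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    raise ConfigurationError(
        f"unknown classifier kind {kind!r}; choose from {CLASSIFIER_KINDS}"
    )


def fit_classifier(features: np.ndarray, labels, kind: str = "lda") -> Classifier:
    """Fit a backend of the given ``kind`` on a feature matrix."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"features {X.shape} do not match {y.shape[0]} labels")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to fit a classifier")

    # Degenerate geometry (all rows identical) breaks every backend's
    # decision rule; declare the majority class, lowest label on ties.
    if np.allclose(X, X[0]):
        best = classes[counts == counts.max()].min()
        return Classifier(kind=kind, estimator=None, classes=classes,
                          n_features=X.shape[1], fallback_label=int(best))

    est = _make_estimator(kind)
    k = getattr(est, "n_neighbors", None)
    if k is not None and X.shape[0] < k:
        est.set_params(n_neighbors=X.shape[0])
    est.fit(X, y)
    return Classifier(kind=kind, estimator=est, classes=classes,
                      n_features=X.shape[1])


def predict(clf: Classifier, features: np.ndarray) -> np.ndarray:
    """Predict one label per feature row."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != clf.n_features:
        raise ValueError(
            f"feature matrix {X.shape} does not match {clf.n_features} "
            "training features"
        )
    if X.shape[0] == 0:
        return np.empty(0, dtype=clf.classes.dtype)
    if clf.estimator is None:
        return np.full(X.shape[0], clf.fallback_label, dtype=clf.classes.dtype)
    return clf.estimator.predict(X)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary (one-vs-rest) confusion counts for one positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


def confusion(y_true, y_pred, positive_class) -> ConfusionCounts:
    """Count TP/FP/TN/FN treating ``positive_class`` as the positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    t = y_true == positive_class
    p = y_pred == positive_class
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def accuracy(y_true, y_pred) -> float:
    """Exact-match fraction over trials (multi-class)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size == 0:
        raise ValueError("accuracy of an empty prediction set is undefined")
    return float(np.mean(y_true == y_pred))


def chance_level(y_true, y_pred=None, method: str = "uniform") -> float:
    """Chance agreement ``p_e`` for Cohen's kappa.

    ``"uniform"`` (default): ``1/n_classes``, the balanced-design
    convention. ``"marginal"``: the product of empirical marginals summed
    over classes (Cohen's original estimate; requires ``y_pred``).
    """
    y_true = np.asarray(y_true)
    if method == "uniform":
        return 1.0 / np.unique(y_true).size
    if method == "marginal":
        if y_pred is None:
            raise ValueError("marginal chance level requires predictions")
        y_pred = np.asarray(y_pred)
        n = y_true.size
        classes = np.union1d(y_true, y_pred)
        return float(sum(
            (np.sum(y_true == c) / n) * (np.sum(y_pred == c) / n) for c in classes
        ))
    raise ConfigurationError(f"unknown chance method {method!r}")


def cohen_kappa(acc: float, p_e: float) -> float:
    """Chance-corrected agreement: ``(acc - p_e) / (1 - p_e)``."""
    if not 0.0 <= p_e < 1.0:
        raise ValueError(f"chance level p_e must be in [0, 1), got {p_e}")
    return (acc - p_e) / (1.0 - p_e)


@dataclass(frozen=True)
class Metrics:
    """Accuracy and kappa of one evaluation, with the chance level used."""

    acc: float
    kappa: float
    p_e: float
    n_trials: int


def evaluate_predictions(y_true, y_pred, p_e: float | None = None) -> Metrics:
    """Accuracy + kappa of a prediction set (``p_e`` defaults to uniform)."""
    acc = accuracy(y_true, y_pred)
    if p_e is None:
        p_e = chance_level(y_true)
    return Metrics(acc=acc, kappa=cohen_kappa(acc, p_e), p_e=p_e,
                   n_trials=np.asarray(y_true).size)


def summarize(values) -> tuple[float, float]:
    """Mean and sample standard deviation (n-1 denominator) of a list."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarize an empty list")
    mean = float(values.mean())
    std = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return mean, std
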