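"""Classifier families and the F1 metric used throughout the pipeline.

Two model families are supported: soft-margin SVMs (radial or linear
kernel) and maximum-likelihood LDA with a pooled covariance estimate.
Performance everywhere is the support-weighted one-vs-rest F1 score; for
balanced binary labels 0.5 is the random-performance anchor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import f1_score
from sklearn.svm import SVC

__all__ = ["ClassifierSpec", "train", "predict", "weighted_ovr_f1"]

_KINDS = ("svm_rbf", "svm_linear", "lda")


@dataclass(frozen=True)
class ClassifierSpec:
    """Model family plus the few hyperparameters that matter.

    ``C`` is the SVM soft-margin penalty; the RBF kernel width follows the
    variance-scaled convention gamma = 1 / (n_features * Var(X)).  LDA uses
    plain maximum-likelihood estimates (no shrinkage) by default; set
    ``lda_shrinkage`` for p > n edge cases.
    """

    kind: str = "svm_rbf"
    C: float = 1.0
    lda_shrinkage: bool = False

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}; expected {_KINDS}")
        if self.C <= 0:
            raise ValueError("C must be positive")


def train(spec: ClassifierSpec, X, y):
    """Fit a classifier on an (n_samples, n_features) matrix.

    Multi-class SVMs use one-vs-one voting internally (libsvm default);
    the reported metric stays one-vs-rest regardless.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n_samples, n_features) matching y")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training labels contain a single class")
    if X.shape[0] < classes.size:
        raise ValueError("need at least as many samples as classes")
    if spec.kind == "svm_rbf":
        clf = SVC(kernel="rbf", C=spec.C, gamma="scale")
    elif spec.kind == "svm_linear":
        clf = SVC(kernel="linear", C=spec.C)
    else:
        if spec.lda_shrinkage:
            clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        else:
            clf = LinearDiscriminantAnalysis(solver="svd")
    return clf.fit(X, y)


def predict(classifier, X) -> np.ndarray:
    """Predict one label per row; empty input gives an empty array."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0, dtype=object)
    expected = getattr(classifier, "n_features_in_", None)
    if expected is not None and X.shape[1] != expected:
        raise ValueError(f"feature count mismatch: model expects {expected}, "
                         f"got {X.shape[1]}")
    return classifier.predict(X)


def weighted_ovr_f1(y_true, y_pred) -> float:
    """Support-weighted mean of per-class one-vs-rest F1 scores.

    Classes with zero precision+recall contribute F1 = 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    if y_true.size == 0:
        raise ValueError("need at least one sample")
    return float(f1_score(y_true, y_pred, average="weighted", zero_division=0))
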