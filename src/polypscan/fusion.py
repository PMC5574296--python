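"""Feature fusion and linear-SVM classification.

The 144 color-wavelet features and 4096 CNN features of a window are
concatenated into one 4240-element vector, z-scored per feature (the two
blocks live on incompatible scales and a margin classifier is
scale-sensitive), and classified by a linear support vector machine
(squared-hinge loss, one-vs-rest for more than two classes).  The signed
distance to the separating hyperplane serves as the window score used by
marker aggregation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC
from sklearn.utils.validation import check_is_fitted

from .exceptions import DataError, DegenerateLabelsError, ShapeError
from .wavelet import N_FEATURES as N_CW_FEATURES
from .cnn import N_CNN_FEATURES

N_FUSED_FEATURES = N_CW_FEATURES + N_CNN_FEATURES  # 4240


def fuse(cw: np.ndarray, cnn: np.ndarray) -> np.ndarray:
    """Concatenate color-wavelet (144) and CNN (4096) features, CW block first.

    Accepts single vectors or matching (n, k) matrices.
    """
    cw = np.asarray(cw, dtype=np.float64)
    cnn = np.asarray(cnn, dtype=np.float64)
    if cw.shape[-1] != N_CW_FEATURES:
        raise ShapeError(f"color-wavelet block must have {N_CW_FEATURES} features, got {cw.shape[-1]}")
    if cnn.shape[-1] != N_CNN_FEATURES:
        raise ShapeError(f"CNN block must have {N_CNN_FEATURES} features, got {cnn.shape[-1]}")
    return np.concatenate([cw, cnn], axis=-1)


def fit_scaler(features: np.ndarray) -> StandardScaler:
    """Per-feature mean/std scaler; constant features get unit scale."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2 or features.shape[0] < 2:
        raise DataError("scaler fitting needs a 2-D matrix with at least 2 samples")
    return StandardScaler().fit(features)


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion-matrix summary of a binary (or one-vs-rest) evaluation."""

    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: object
    per_class: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        """True-positive rate TP / (TP + FN)."""
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def specificity(self) -> float:
        """True-negative rate TN / (TN + FP)."""
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else 0.0

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "positive_class": str(self.positive_class),
                "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
                "accuracy": self.accuracy,
            },
            indent=2,
        )

    def format_confusion(self) -> str:
        """Plain-text 2×2 confusion matrix (rows: truth, columns: prediction)."""
        pos = str(self.positive_class)
        w = max(len(pos) + 4, 12)
        lines = [
            f"{'':>{w}}{pos:>{w}}{'not ' + pos:>{w}}",
            f"{pos:>{w}}{self.tp:>{w}}{self.fn:>{w}}",
            f"{'not ' + pos:>{w}}{self.fp:>{w}}{self.tn:>{w}}",
        ]
        return "\n".join(lines)


def evaluate(predictions, truth, positive_class=1) -> EvalMetrics:
    """Confusion matrix and sensitivity/specificity/accuracy.

    For multiclass labels the metrics are one-vs-rest with respect to
    ``positive_class``; ``per_class`` carries the one-vs-rest counts of every
    label present in the truth.
    """
    y_pred = np.asarray(predictions)
    y_true = np.asarray(truth)
    if y_pred.shape != y_true.shape:
        raise ShapeError(f"prediction/truth length mismatch: {y_pred.shape} vs {y_true.shape}")
    labels = set(np.unique(y_true)) | set(np.unique(y_pred))
    if positive_class not in labels:
        raise DataError(f"positive class {positive_class!r} absent from labels {sorted(map(str, labels))}")

    def counts(cls):
        pp = y_pred == cls
        tp_ = y_true == cls
        return dict(
            tp=int(np.sum(pp & tp_)),
            fp=int(np.sum(pp & ~tp_)),
            fn=int(np.sum(~pp & tp_)),
            tn=int(np.sum(~pp & ~tp_)),
        )

    per_class = {cls: counts(cls) for cls in sorted(np.unique(y_true).tolist())}
    c = counts(positive_class)
    return EvalMetrics(positive_class=positive_class, per_class=per_class, **c)


class FusedPolypClassifier(ClassifierMixin, BaseEstimator):
    """Linear SVM on z-scored fused (color-wavelet + CNN) feature vectors.

    Parameters
    ----------
    C : float, default 1.0
        Inverse regularization strength of the squared-hinge linear SVM.
    random_state : int, default 0
        Seed for the liblinear solver (deterministic given a fixed seed).
    validate_length : bool, default True
        Require inputs of exactly 4240 features.  Disable to reuse the
        classifier on a single feature family (ablation experiments).

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels; one-vs-rest hyperplanes for more than two.
    coef_, intercept_ : ndarray
        Hyperplane parameters in the *scaled* feature space.
    scaler_ : StandardScaler
        Per-feature standardization fitted on the training features.
    """

    def __init__(self, C: float = 1.0, random_state: int = 0, validate_length: bool = True):
        self.C = C
        self.random_state = random_state
        self.validate_length = validate_length

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        if self.validate_length and X.shape[1] != N_FUSED_FEATURES:
            raise ShapeError(f"fused feature vectors must have {N_FUSED_FEATURES} entries, got {X.shape[1]}")
        if hasattr(self, "scaler_") and X.shape[1] != self.scaler_.mean_.shape[0]:
            raise ShapeError(f"expected {self.scaler_.mean_.shape[0]} features, got {X.shape[1]}")
        if not np.all(np.isfinite(X)):
            raise DataError("feature matrix contains non-finite values")
        return X

    def fit(self, X, y):
        X = self._check_X(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise DegenerateLabelsError("SVM training requires at least two classes")
        self.scaler_ = fit_scaler(X)
        Xs = self.scaler_.transform(X)
        self.svc_ = LinearSVC(C=self.C, loss="squared_hinge", random_state=self.random_state)
        self.svc_.fit(Xs, y)
        self.classes_ = self.svc_.classes_
        self.coef_ = self.svc_.coef_
        self.intercept_ = self.svc_.intercept_
        return self

    def decision_function(self, X) -> np.ndarray:
        """Signed score w·x + b in the scaled space; positive = polyp side
        for binary models (score for the larger class label)."""
        check_is_fitted(self, "svc_")
        return self.svc_.decision_function(self.scaler_.transform(self._check_X(X)))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "svc_")
        return self.svc_.predict(self.scaler_.transform(self._check_X(X)))

    def predict_with_scores(self, X):
        """(labels, signed score of the winning hyperplane) per sample."""
        scores = self.decision_function(self._check_X(X))
        if scores.ndim == 1:  # binary: sign picks the class
            labels = self.classes_[(scores > 0).astype(int)]
            win = scores
        else:
            idx = scores.argmax(axis=1)
            labels = self.classes_[idx]
            win = scores[np.arange(len(idx)), idx]
        return labels, win

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self, "svc_")
        meta = {"params": self.get_params(), "classes": self.classes_.tolist()}
        np.savez_compressed(
            path,
            meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            coef=self.svc_.coef_,
            intercept=self.svc_.intercept_,
            scaler_mean=self.scaler_.mean_,
            scaler_scale=self.scaler_.scale_,
        )

    @classmethod
    def load(cls, path) -> "FusedPolypClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            est = cls(**meta["params"])
            classes = np.asarray(meta["classes"])
            est.svc_ = LinearSVC(C=est.C, loss="squared_hinge", random_state=est.random_state)
            est.svc_.coef_ = data["coef"]
            est.svc_.intercept_ = data["intercept"]
            est.svc_.classes_ = classes
            est.classes_ = classes
            est.coef_ = est.svc_.coef_
            est.intercept_ = est.svc_.intercept_
            scaler = StandardScaler()
            scaler.mean_ = data["scaler_mean"]
            scaler.scale_ = data["scaler_scale"]
            scaler.var_ = scaler.scale_ ** 2
            scaler.n_features_in_ = scaler.mean_.shape[0]
            scaler.with_mean = scaler.with_std = True
            est.scaler_ = scaler
        return est
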