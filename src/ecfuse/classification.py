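"""Probabilistic base classifiers and the multi-label second stage.

Two base methods produce class-probability vectors over the six EC classes:

* ``"svm"`` -- an RBF-kernel support vector machine with pairwise-coupled
  probability calibration (scikit-learn's ``SVC(probability=True)``).
* ``"nn"`` -- a nearest-neighbor rule. Hard prediction is the classic
  k-nearest-neighbor vote; probabilities are inverse-distance-weighted votes
  among the k neighbors. For k = 1 that vote is degenerate (a one-hot
  vector), so the k = 1 probability surrogate is a softmax over the negative
  distances to the nearest training sample of each class, which preserves
  the 1-NN hard decision while remaining informative for fusion.

Multi-label prediction uses binary relevance: six independent binary
classifiers (one per EC class, sharing the base method) on the fused
6-dimensional probability input. If all six relevance outputs are 0 the
prediction falls back to a one-hot vector at the most probable fused class,
because every enzyme carries at least one function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.svm import SVC

from .sequence_similarity import ClassProbabilityVector, N_CLASSES

__all__ = [
    "LabelVector",
    "TrainedModel",
    "MultiLabelModel",
    "train_single_label",
    "predict_proba",
    "predict_single_label",
    "train_multi_label",
    "predict_multi_label",
]

Method = Literal["svm", "nn"]

#: Temperature (in feature-space distance units) of the 1-NN softmax surrogate.
NN_SOFTMAX_SCALE = 1.0


@dataclass
class LabelVector:
    """Six binary EC-class membership indicators; >= 1 positive for truth."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int).ravel()
        if self.values.size != N_CLASSES:
            raise ValueError(f"expected {N_CLASSES} entries, got {self.values.size}")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("label vector entries must be 0/1")

    @property
    def classes(self) -> list[int]:
        return [i + 1 for i in np.flatnonzero(self.values)]


def _validate_features(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2D")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in feature matrix")
    return X


class _NearestNeighbor:
    """kNN with inverse-distance probability votes (softmax surrogate at k=1)."""

    def __init__(self, k: int = 1, softmax_scale: float = NN_SOFTMAX_SCALE):
        self.k = k
        self.softmax_scale = softmax_scale

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_NearestNeighbor":
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        d = cdist(X, self.X_)
        n_classes = len(self.classes_)
        out = np.zeros((len(X), n_classes))
        if self.k == 1:
            # per-class nearest distance, softmax over negatives; an exact
            # hit gets the full mass (the inverse-distance-weighting limit)
            class_dist = np.empty_like(out)
            for ci, c in enumerate(self.classes_):
                class_dist[:, ci] = d[:, self.y_ == c].min(axis=1)
            hit = class_dist.min(axis=1) == 0.0
            out = np.exp(
                -(class_dist - class_dist.min(axis=1, keepdims=True))
                / self.softmax_scale
            )
            out[hit] = (class_dist[hit] == 0.0).astype(float)
            out /= out.sum(axis=1, keepdims=True)
            return out
        order = np.argsort(d, axis=1, kind="stable")[:, : self.k]
        for row in range(len(X)):
            idx = order[row]
            with np.errstate(divide="ignore"):
                w = 1.0 / d[row, idx]
            if np.isinf(w).any():  # exact hit: all weight on zero-distance neighbors
                w = np.isinf(w).astype(float)
            for j, i in enumerate(idx):
                ci = np.searchsorted(self.classes_, self.y_[i])
                out[row, ci] += w[j]
        out /= out.sum(axis=1, keepdims=True)
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax of the probability vote; ties resolve to the lowest class
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


@dataclass
class TrainedModel:
    """A fitted single-label base classifier with its feature signature."""

    method: Method
    estimator: object
    n_features: int
    classes: np.ndarray  # subset of 1..6 present at training

    def signature_matches(self, X: np.ndarray) -> bool:
        return X.shape[1] == self.n_features


def train_single_label(
    X: np.ndarray,
    y: np.ndarray,
    method: Method = "svm",
    *,
    svm_c: float = 10.0,
    svm_gamma: float | str = "scale",
    nn_k: int = 1,
    random_state: int = 0,
) -> TrainedModel:
    """Fit a single-label classifier on rows of X with classes y in 1..6.

    Raises
    ------
    ValueError
        If fewer than two classes are present or X contains NaN/inf.
    """
    X = _validate_features(X)
    y = np.asarray(y, dtype=int).ravel()
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if method == "svm":
        # SVC(probability=True) performs Platt scaling with pairwise coupling,
        # which is the calibration this model family relies on; silence the
        # sklearn 1.9 deprecation of the flag.
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=FutureWarning)
            est = SVC(
                kernel="rbf",
                C=svm_c,
                gamma=svm_gamma,
                probability=True,
                random_state=random_state,
            ).fit(X, y)
    elif method == "nn":
        est = _NearestNeighbor(k=nn_k).fit(X, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return TrainedModel(method, est, X.shape[1], classes)


def predict_proba(model: TrainedModel, X: np.ndarray) -> list[ClassProbabilityVector]:
    """One six-class probability vector per row; absent classes get 0."""
    X = _validate_features(X)
    if not model.signature_matches(X):
        raise ValueError(
            f"feature signature mismatch: model expects {model.n_features} features, "
            f"got {X.shape[1]}"
        )
    raw = model.estimator.predict_proba(X)
    est_classes = np.asarray(model.estimator.classes_, dtype=int)
    out = np.zeros((len(X), N_CLASSES))
    out[:, est_classes - 1] = raw
    return [ClassProbabilityVector(row) for row in out]


def predict_single_label(probs: ClassProbabilityVector) -> int:
    """Most probable class (1..6); ties break to the lowest class index."""
    return probs.argmax_class()


class _MultiLabelProbEnsemble:
    """Per-class probability base for multi-label training sets.

    For ``svm``: six Platt-calibrated binary RBF-SVMs, one per EC class,
    trained on the class's membership column; row probabilities are the six
    positive-class outputs normalized to sum 1. For ``nn``: the distance to
    the nearest training sample *carrying* each class, passed through a
    softmax over negative distances. Both reduce to the single-label
    constructions when every sample carries exactly one class.
    """

    def __init__(self, method: Method, svm_c: float = 10.0,
                 svm_gamma: float | str = "scale",
                 softmax_scale: float = NN_SOFTMAX_SCALE, random_state: int = 0):
        self.method = method
        self.svm_c = svm_c
        self.svm_gamma = svm_gamma
        self.softmax_scale = softmax_scale
        self.random_state = random_state
        self.classes_ = np.arange(1, N_CLASSES + 1)

    def fit(self, X: np.ndarray, Y: np.ndarray) -> "_MultiLabelProbEnsemble":
        Y = np.asarray(Y, dtype=int)
        if Y.shape != (len(X), N_CLASSES):
            raise ValueError("Y must be an (n, 6) binary matrix")
        if self.method == "svm":
            self.models_ = []
            for j in range(N_CLASSES):
                yj = Y[:, j]
                if yj.min() == yj.max():  # constant column: carry prior
                    self.models_.append(float(yj.mean()))
                    continue
                with warnings.catch_warnings():
                    warnings.filterwarnings("ignore", category=FutureWarning)
                    self.models_.append(
                        SVC(
                            kernel="rbf", C=self.svm_c, gamma=self.svm_gamma,
                            probability=True, random_state=self.random_state,
                        ).fit(X, yj)
                    )
        else:
            self.X_ = np.asarray(X, dtype=float)
            self.Y_ = Y
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        raw = np.zeros((len(X), N_CLASSES))
        if self.method == "svm":
            for j, model in enumerate(self.models_):
                if isinstance(model, float):
                    raw[:, j] = model
                else:
                    pos = list(model.classes_).index(1)
                    raw[:, j] = model.predict_proba(X)[:, pos]
        else:
            d = cdist(X, self.X_)
            for j in range(N_CLASSES):
                carriers = self.Y_[:, j] == 1
                raw[:, j] = (
                    d[:, carriers].min(axis=1) if carriers.any() else np.inf
                )
            raw = np.exp(-(raw - raw.min(axis=1, keepdims=True)) / self.softmax_scale)
        totals = raw.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        return raw / totals


def train_probability_base_multilabel(
    X: np.ndarray,
    Y: np.ndarray,
    method: Method = "svm",
    *,
    svm_c: float = 10.0,
    svm_gamma: float | str = "scale",
    random_state: int = 0,
) -> TrainedModel:
    """Fit the per-class probability base on a multi-label training set.

    The returned model plugs into :func:`predict_proba` like a single-label
    base classifier; its probability rows sum to 1 over the six classes.
    """
    X = _validate_features(X)
    est = _MultiLabelProbEnsemble(
        method, svm_c=svm_c, svm_gamma=svm_gamma, random_state=random_state
    ).fit(X, Y)
    return TrainedModel(method, est, X.shape[1], est.classes_)


@dataclass
class MultiLabelModel:
    """Binary-relevance second stage over fused 6-dim probability inputs."""

    method: Method
    relevance_models: list[object] = field(default_factory=list)
    constant_zero: list[bool] = field(default_factory=list)

    def predict(self, P: np.ndarray, fallback_probs: np.ndarray | None = None) -> np.ndarray:
        """Predict 6-bit label vectors for rows of fused probabilities.

        Rows whose six relevance outputs are all zero fall back to a one-hot
        vector at the most probable class — taken from ``fallback_probs``
        (n, 6) when given, else from the input rows themselves (valid when
        the inputs are the fused 6-dim probabilities).
        """
        P = _validate_features(P)
        ranks = P if fallback_probs is None else np.asarray(fallback_probs, float)
        if ranks.shape != (len(P), N_CLASSES):
            raise ValueError("fallback probabilities must be an (n, 6) matrix")
        Y = np.zeros((len(P), N_CLASSES), dtype=int)
        for j in range(N_CLASSES):
            if not self.constant_zero[j]:
                Y[:, j] = self.relevance_models[j].predict(P)
        empty = Y.sum(axis=1) == 0
        if empty.any():
            Y[empty, ranks[empty].argmax(axis=1)] = 1
        return Y


def train_multi_label(
    P: np.ndarray,
    Y: np.ndarray,
    method: Method = "svm",
    *,
    svm_c: float = 10.0,
    svm_gamma: float | str = "scale",
    nn_k: int = 1,
    random_state: int = 0,
) -> MultiLabelModel:
    """Fit six independent binary relevance classifiers on probability inputs.

    ``P`` holds fused class-probability rows (each summing to 1) and ``Y``
    the 6-bit true label vectors. A class with no positive training example
    yields a constant-zero relevance model (with a warning).
    """
    P = _validate_features(P)
    Y = np.asarray(Y, dtype=int)
    if Y.shape != (len(P), N_CLASSES):
        raise ValueError(f"label matrix shape {Y.shape} does not match {len(P)} rows")
    if (Y.sum(axis=1) == 0).any():
        raise ValueError("a training label vector has no positive entry")
    models: list[object] = []
    constant_zero: list[bool] = []
    for j in range(N_CLASSES):
        yj = Y[:, j]
        if yj.sum() == 0:
            warnings.warn(
                f"EC class {j + 1} has no positive training sample; "
                "its relevance model predicts constant 0"
            )
            models.append(None)
            constant_zero.append(True)
            continue
        if yj.sum() == len(yj):  # constant-positive class
            models.append(_Constant(1))
            constant_zero.append(False)
            continue
        if method == "svm":
            est = SVC(kernel="rbf", C=svm_c, gamma=svm_gamma, random_state=random_state)
        elif method == "nn":
            est = _NearestNeighbor(k=nn_k)
        else:
            raise ValueError(f"unknown method {method!r}")
        models.append(est.fit(P, yj))
        constant_zero.append(False)
    return MultiLabelModel(method, models, constant_zero)


class _Constant:
    def __init__(self, value: int):
        self.value = value

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), self.value, dtype=int)


def predict_multi_label(
    model: MultiLabelModel, P: np.ndarray, fallback_probs: np.ndarray | None = None
) -> np.ndarray:
    """Convenience wrapper around :meth:`MultiLabelModel.predict`."""
    return model.predict(P, fallback_probs=fallback_probs)
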