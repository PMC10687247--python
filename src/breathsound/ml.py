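"""Machine-learning classifiers: SVM, kNN (on MFCC vectors) and the CNN.

SVM kernels are the 3rd-degree polynomial and RBF; kNN uses
k in {3, 5, 7} with Euclidean distance on standardized features.  Both
run in a binary (normal/abnormal) or three-class mode.  The CNN consumes
fixed-size spectrogram images (see :mod:`breathsound.cnn`) with the
original batch size of 32; the iteration budget is scaled down from the
original 200,000 to a desk-scale default of 2,000 and is configurable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import joblib
import numpy as np
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cnn import BreathCNN
from .labels import BINARY_LABELS, CLASS_LABELS, to_binary

__all__ = ["MLConfig", "TrainedModel", "train", "predict", "save_model", "load_model"]

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class MLConfig:
    """Model choice and hyper-parameters.

    Compatibility rules: ``cnn`` requires ``spectrogram`` features;
    ``svm``/``knn`` require an MFCC variant.  ``knn_k`` is restricted to
    the odd values 3, 5 and 7.
    """

    model: str = "svm"
    svm_kernel: str = "rbf"  # 'poly3' or 'rbf'
    knn_k: int = 3
    feature_variant: str = "mfcc20"  # 'mfcc20' | 'mfcc40' | 'spectrogram'
    task: str = "three_class"  # 'binary' | 'three_class'
    cnn_batch_size: int = 32
    cnn_max_steps: int = 2000
    cnn_input_size: int = 128
    cnn_channels: tuple[int, ...] = (8, 16, 32, 32)
    cnn_lr: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("svm", "knn", "cnn"):
            raise ValueError(f"model must be svm, knn or cnn, got {self.model!r}")
        if self.svm_kernel not in ("poly3", "rbf"):
            raise ValueError(f"svm_kernel must be 'poly3' or 'rbf', got {self.svm_kernel!r}")
        if self.knn_k not in (3, 5, 7):
            raise ValueError(f"knn_k must be 3, 5 or 7, got {self.knn_k}")
        if self.feature_variant not in ("mfcc20", "mfcc40", "spectrogram"):
            raise ValueError(f"unknown feature_variant {self.feature_variant!r}")
        if self.task not in ("binary", "three_class"):
            raise ValueError(f"task must be 'binary' or 'three_class', got {self.task!r}")
        if self.model == "cnn" and self.feature_variant != "spectrogram":
            raise ValueError("the CNN consumes spectrogram images, not MFCC vectors")
        if self.model in ("svm", "knn") and self.feature_variant == "spectrogram":
            raise ValueError(f"{self.model} consumes MFCC vectors, not spectrogram images")
        if self.cnn_batch_size < 1 or self.cnn_max_steps < 1:
            raise ValueError("cnn_batch_size and cnn_max_steps must be >= 1")

    def with_(self, **kwargs) -> "MLConfig":
        return replace(self, **kwargs)


@dataclass
class TrainedModel:
    """Fitted estimator plus everything needed to reproduce predictions."""

    estimator: object
    config: MLConfig
    classes_: list[str]
    n_features: tuple[int, ...]
    fingerprint: str
    format_version: int = field(default=_FORMAT_VERSION)


def _fingerprint(features: np.ndarray, labels: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(features).tobytes())
    h.update(",".join(map(str, labels)).encode())
    return h.hexdigest()[:16]


def _task_labels(labels, task: str) -> np.ndarray:
    labels = np.asarray(labels)
    if task == "binary":
        return np.asarray(to_binary(list(labels)))
    return labels


def _class_order(task: str, present: set[str]) -> list[str]:
    order = BINARY_LABELS if task == "binary" else CLASS_LABELS
    return [c for c in order if c in present]


def train(features, labels, config: MLConfig | None = None) -> TrainedModel:
    """Fit the configured model.

    ``features`` is (n, d) for svm/knn or (n, s, s) images for the CNN;
    ``labels`` are NS/VS/SS strings (collapsed internally for the binary
    task).  Training is deterministic given ``config.seed``.
    """
    config = config or MLConfig()
    X = np.asarray(features, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    y = _task_labels(labels, config.task)
    present = set(map(str, y))
    if len(present) < 2:
        raise ValueError("training set must contain at least two classes")
    classes = _class_order(config.task, present)
    y_idx = np.array([classes.index(str(v)) for v in y])

    if config.model == "cnn":
        est = BreathCNN(
            n_classes=len(classes),
            input_size=config.cnn_input_size,
            channels=config.cnn_channels,
            lr=config.cnn_lr,
            batch_size=config.cnn_batch_size,
            max_steps=config.cnn_max_steps,
            seed=config.seed,
        ).fit(X, y_idx)
    else:
        if X.ndim != 2:
            raise ValueError(f"{config.model} expects 2-D feature matrix, got shape {X.shape}")
        if config.model == "svm":
            kernel = {"poly3": dict(kernel="poly", degree=3), "rbf": dict(kernel="rbf")}[
                config.svm_kernel
            ]
            clf = SVC(random_state=config.seed, **kernel)
        else:
            clf = KNeighborsClassifier(n_neighbors=config.knn_k)
        est = Pipeline([("scale", StandardScaler()), ("clf", clf)])
        est.fit(X, y_idx)

    return TrainedModel(
        estimator=est,
        config=config,
        classes_=classes,
        n_features=X.shape[1:],
        fingerprint=_fingerprint(X, y),
    )


def _score_matrix(estimator, X: np.ndarray) -> np.ndarray:
    """Per-class scores in (0, 1) rows summing to one.

    kNN and the CNN expose calibrated ``predict_proba``; the SVM scores
    are a softmax of its decision values (any strictly monotone map
    preserves rankings and therefore the ROC/AUC).
    """
    clf = estimator.named_steps["clf"] if isinstance(estimator, Pipeline) else estimator
    if hasattr(clf, "predict_proba"):
        return estimator.predict_proba(X)
    d = estimator.decision_function(X)
    if d.ndim == 1:
        d = np.stack([-d, d], axis=1)
    d = d - d.max(axis=1, keepdims=True)
    e = np.exp(d)
    return e / e.sum(axis=1, keepdims=True)


def predict(model: TrainedModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Labels and per-class scores for new cycles.

    Returns ``(labels, scores)`` where ``scores[:, j]`` scores class
    ``model.classes_[j]`` (rows sum to one; labels are the row argmax);
    for the binary task the abnormal-class column is the ROC score.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[1:] != model.n_features:
        raise ValueError(
            f"feature shape {X.shape[1:]} does not match training shape {model.n_features}"
        )
    proba = _score_matrix(model.estimator, X)
    idx = np.argmax(proba, axis=1)
    labels = np.array([model.classes_[i] for i in idx])
    return labels, proba


def abnormal_scores(model: TrainedModel, proba: np.ndarray) -> np.ndarray:
    """Column of ``proba`` giving the abnormal-class score (binary task)."""
    if model.config.task != "binary":
        raise ValueError("abnormal scores are defined for the binary task")
    return proba[:, model.classes_.index("abnormal")]


def save_model(model: TrainedModel, path) -> None:
    joblib.dump({"format_version": _FORMAT_VERSION, "model": model}, path)


def load_model(path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"unsupported model file version {payload.get('format_version')!r}"
        )
    return payload["model"]
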