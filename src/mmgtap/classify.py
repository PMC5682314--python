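"""Gesture classifiers and cross-validated evaluation.

Three standard classifiers are compared on the singular-value features:
Gaussian naive Bayes (NBC), K-nearest neighbours (KNN), and a support vector
machine (SVM) with the polynomial kernel

    G(x, z) = (gamma * <x, z> + coef0) ** degree,     gamma=1, coef0=0, degree=3.

scikit-learn provides the estimators; this module owns the evaluation
protocol: stratified k-fold cross-validation in which F-value feature
ranking and z-scoring are fitted on each training fold only (no selection
leakage), per-fold confusion matrices are aggregated, and the whole report
is a pure function of (data, spec, seed).

Tie rules: class labels are ordered (thumb=0 .. little=4) and every argmax
tie resolves to the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import Convention, f_value_ranking, select_features

__all__ = [
    "ClassifierSpec",
    "EvaluationReport",
    "polynomial_kernel",
    "make_classifier",
    "train",
    "predict",
    "cross_validate",
    "sweep_feature_count",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Which classifier to run and its hyperparameters.

    ``standardize`` z-scores features with training-fold statistics for KNN
    and SVM; NBC consumes raw features (its Gaussian likelihood already
    normalises per-feature scale).
    """

    kind: Literal["nbc", "knn", "svm"] = "nbc"
    knn_k: int = 5
    svm_c: float = 1.0
    svm_gamma: float = 1.0
    svm_coef0: float = 0.0
    svm_degree: int = 3
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("nbc", "knn", "svm"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.knn_k < 1 or self.knn_k % 2 == 0:
            raise ValueError(f"knn_k must be odd and >= 1, got {self.knn_k}")
        if self.svm_degree < 1:
            raise ValueError("svm_degree must be >= 1")
        if self.svm_c <= 0:
            raise ValueError("svm_c must be > 0")


@dataclass
class EvaluationReport:
    """Aggregated cross-validation outcome."""

    classes: list[int]
    confusion: np.ndarray
    accuracy: float
    per_class_accuracy: dict[int, float]
    fold_accuracies: list[float]
    n_samples: int
    selected_indices: Optional[list[list[list[int]]]] = None  # per fold, per channel
    spec: Optional[ClassifierSpec] = None
    seed: Optional[int] = None
    folds: int = 5

    def to_dict(self) -> dict:
        """JSON-serialisable view (used for byte-stable reports)."""
        out = {
            "classes": [int(c) for c in self.classes],
            "confusion": self.confusion.astype(int).tolist(),
            "accuracy": float(self.accuracy),
            "per_class_accuracy": {
                str(k): float(v) for k, v in self.per_class_accuracy.items()
            },
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "n_samples": int(self.n_samples),
            "folds": int(self.folds),
            "seed": self.seed,
        }
        if self.selected_indices is not None:
            out["selected_indices"] = [
                [[int(i) for i in ch] for ch in fold]
                for fold in self.selected_indices
            ]
        if self.spec is not None:
            out["classifier"] = {
                "kind": self.spec.kind,
                "knn_k": self.spec.knn_k,
                "svm_c": self.spec.svm_c,
                "svm_gamma": self.spec.svm_gamma,
                "svm_coef0": self.spec.svm_coef0,
                "svm_degree": self.spec.svm_degree,
                "standardize": self.spec.standardize,
            }
        return out


def polynomial_kernel(
    x: np.ndarray,
    z: np.ndarray,
    gamma: float = 1.0,
    coef0: float = 0.0,
    degree: int = 3,
) -> float:
    """``(gamma * <x, z> + coef0) ** degree`` for two feature vectors."""
    x = np.asarray(x, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    if x.shape != z.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {z.shape}")
    return float((gamma * np.dot(x, z) + coef0) ** degree)


def make_classifier(spec: ClassifierSpec):
    """Fresh (unfitted) scikit-learn estimator for ``spec``."""
    if spec.kind == "nbc":
        return GaussianNB(var_smoothing=1e-9)
    if spec.kind == "knn":
        est = KNeighborsClassifier(n_neighbors=spec.knn_k)
    else:
        est = SVC(
            kernel="poly",
            degree=spec.svm_degree,
            gamma=spec.svm_gamma,
            coef0=spec.svm_coef0,
            C=spec.svm_c,
            shrinking=False,
            tol=1e-3,
        )
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("clf", est)])
    return est


def _validate_labels(y: np.ndarray, min_per_class: int = 2) -> np.ndarray:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("classification needs at least 2 classes")
    low = classes[counts < min_per_class]
    if low.size:
        raise ValueError(
            f"class(es) {low.tolist()} have fewer than {min_per_class} samples"
        )
    return classes


def train(x: np.ndarray, y: np.ndarray, spec: ClassifierSpec):
    """Fit one classifier on labelled feature vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    # one sample per class is enough to fit (KNN k=1 is exactly Voronoi;
    # the NBC variance floor covers degenerate variances)
    _validate_labels(y, min_per_class=1)
    model = make_classifier(spec)
    model.fit(x, y)
    return model


def predict(model, x: np.ndarray) -> np.ndarray:
    """Deterministic label per sample; dimension mismatches raise."""
    return model.predict(np.asarray(x, dtype=np.float64))


def _split_channels(x: np.ndarray, n_channels: int) -> list[np.ndarray]:
    if x.shape[1] % n_channels != 0:
        raise ValueError(
            f"{x.shape[1]} features do not split into {n_channels} channels"
        )
    w = x.shape[1] // n_channels
    return [x[:, c * w : (c + 1) * w] for c in range(n_channels)]


def cross_validate(
    x: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    folds: int = 5,
    seed: int = 0,
    k_per_channel: Optional[int] = None,
    n_channels: int = 2,
    convention: Convention = "fisher",
) -> EvaluationReport:
    """Stratified k-fold evaluation with per-fold feature selection.

    When ``k_per_channel`` is given, ``x`` is treated as the concatenation of
    ``n_channels`` equal per-channel blocks; an F-value ranking is fitted on
    each training fold per channel and the top-k features per channel are
    used.  With ``k_per_channel=None`` all features are used as-is.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    classes = _validate_labels(y, min_per_class=folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    conf = np.zeros((classes.size, classes.size), dtype=np.int64)
    fold_acc: list[float] = []
    selected: list[list[list[int]]] = []
    for train_idx, test_idx in skf.split(x, y):
        x_tr, x_te = x[train_idx], x[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]
        if k_per_channel is not None:
            blocks_tr = _split_channels(x_tr, n_channels)
            blocks_te = _split_channels(x_te, n_channels)
            rankings = [
                f_value_ranking(b, y_tr, convention=convention) for b in blocks_tr
            ]
            idx_per_ch = select_features(rankings, k_per_channel)
            selected.append([list(map(int, idx)) for idx in idx_per_ch])
            x_tr = np.hstack(
                [b[:, idx] for b, idx in zip(blocks_tr, idx_per_ch)]
            )
            x_te = np.hstack(
                [b[:, idx] for b, idx in zip(blocks_te, idx_per_ch)]
            )
        model = train(x_tr, y_tr, spec)
        pred = predict(model, x_te)
        conf += confusion_matrix(y_te, pred, labels=classes)
        fold_acc.append(float(np.mean(pred == y_te)))

    total = int(conf.sum())
    accuracy = float(np.trace(conf) / total)
    per_class = {
        int(c): float(conf[i, i] / conf[i].sum()) if conf[i].sum() else 0.0
        for i, c in enumerate(classes)
    }
    return EvaluationReport(
        classes=[int(c) for c in classes],
        confusion=conf,
        accuracy=accuracy,
        per_class_accuracy=per_class,
        fold_accuracies=fold_acc,
        n_samples=total,
        selected_indices=selected if k_per_channel is not None else None,
        spec=spec,
        seed=seed,
        folds=folds,
    )


def sweep_feature_count(
    x: np.ndarray,
    y: np.ndarray,
    specs: Sequence[ClassifierSpec],
    k_values: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    n_channels: int = 2,
    convention: Convention = "fisher",
):
    """Cross-validated accuracy per (classifier, k features/channel).

    Returns a tidy :class:`pandas.DataFrame` with columns
    ``classifier, k_per_channel, accuracy`` — one row per combination.
    """
    import pandas as pd

    rows = []
    for spec in specs:
        for k in k_values:
            rep = cross_validate(
                x,
                y,
                spec,
                folds=folds,
                seed=seed,
                k_per_channel=int(k),
                n_channels=n_channels,
                convention=convention,
            )
            rows.append(
                {
                    "classifier": spec.kind,
                    "k_per_channel": int(k),
                    "accuracy": rep.accuracy,
                }
            )
    return pd.DataFrame(rows)
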