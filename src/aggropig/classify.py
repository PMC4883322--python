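"""Hierarchical two-stage SVM detection and classification.

Stage 1 separates aggressive from normal episodes with a polynomial
kernel (C = 4.5); episodes judged aggressive move to stage 2, an RBF
machine (C = 4.5, gamma = 3.5) separating head/body knocking from
chasing. Kernels, per-fold z-score standardization, the hierarchy,
stratified cross-validation and the confusion-derived rates are all
implemented here; only the quadratic-program solver is delegated (to
scikit-learn's SVC via a precomputed Gram matrix).

Detection is scored with the aggression detection rate
ADR = TP/(TP+FN) x 100, the false positive rate FP/(FP+TN) x 100 and
the false negative rate FN/(TP+FN) x 100; classification with per-class
precision TP/(TP+FP) x 100 and recall TP/(TP+FN) x 100 plus their
unweighted (macro) means. Displayed rates are rounded half-up to one
decimal; full precision is kept internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "KernelSpec",
    "SvmModel",
    "DetectionMetrics",
    "ClassMetrics",
    "STAGE1_KERNEL",
    "STAGE2_KERNEL",
    "kernel_eval",
    "gram_matrix",
    "train_svm",
    "predict_hierarchical",
    "cross_validate",
    "detection_metrics",
    "classification_metrics",
    "display_round",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and hyperparameters for one SVM stage."""

    kind: str  # "polynomial" | "rbf"
    C: float = 4.5
    gamma: float | None = None  # rbf width
    degree: int = 3
    coef0: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("polynomial", "rbf"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.kind == "rbf" and (self.gamma is None or self.gamma <= 0):
            raise ValueError("rbf kernel requires gamma > 0")
        if self.degree < 1:
            raise ValueError("degree must be >= 1")


#: Detection stage: polynomial kernel, C = 4.5 (degree/coef0 configurable).
STAGE1_KERNEL = KernelSpec(kind="polynomial", C=4.5, degree=3, coef0=1.0)
#: Classification stage: RBF kernel, C = 4.5, gamma = 3.5.
STAGE2_KERNEL = KernelSpec(kind="rbf", C=4.5, gamma=3.5)


def kernel_eval(spec: KernelSpec, x: np.ndarray, y: np.ndarray) -> float:
    """K(x, y) for a single pair of feature vectors.

    rbf: exp(-gamma * ||x - y||^2); polynomial: (x.y + coef0)^degree.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if spec.kind == "rbf":
        return float(np.exp(-spec.gamma * np.sum((x - y) ** 2)))
    return float((np.dot(x, y) + spec.coef0) ** spec.degree)


def gram_matrix(spec: KernelSpec, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Kernel matrix K[i, j] = K(X[i], Y[j]), vectorized."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.asarray(Y, dtype=np.float64)
    if spec.kind == "rbf":
        sq = (
            np.sum(X**2, axis=1)[:, None]
            + np.sum(Y**2, axis=1)[None, :]
            - 2 * X @ Y.T
        )
        return np.exp(-spec.gamma * np.clip(sq, 0.0, None))
    return (X @ Y.T + spec.coef0) ** spec.degree


@dataclass
class SvmModel:
    """A trained binary SVM stage with its standardization parameters.

    Features are z-scored with the training-set mean/SD before kernel
    evaluation, so the kernel hyperparameters keep their meaning across
    unit choices (px vs cm). Prediction returns labels in {-1, +1}.
    """

    kernel: KernelSpec
    feature_mean: np.ndarray = field(repr=False, default=None)
    feature_sd: np.ndarray = field(repr=False, default=None)
    _svc: SVC = field(repr=False, default=None)
    _X_train: np.ndarray = field(repr=False, default=None)

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.feature_mean) / self.feature_sd

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = self.standardize(np.atleast_2d(X))
        return self._svc.decision_function(gram_matrix(self.kernel, Z, self._X_train))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels in {-1, +1} for rows of X."""
        return np.where(self.decision_function(X) >= 0, 1, -1)


def train_svm(X: np.ndarray, y: np.ndarray, spec: KernelSpec) -> SvmModel:
    """Fit one SVM stage on labels in {-1, +1}.

    Standardization parameters come from the training set; a feature
    with zero spread standardizes to 0 (SD clamped to 1).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if set(np.unique(y)) != {-1, 1}:
        raise ValueError("training requires both labels -1 and +1")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    model = SvmModel(kernel=spec, feature_mean=mean, feature_sd=sd)
    Z = model.standardize(X)
    svc = SVC(kernel="precomputed", C=spec.C)
    svc.fit(gram_matrix(spec, Z, Z), y.astype(int))
    model._svc = svc
    model._X_train = Z
    return model


def predict_hierarchical(
    stage1: SvmModel, stage2: SvmModel, X: np.ndarray
) -> np.ndarray:
    """Cascade the two stages over rows of X.

    Stage 1 (+1 = aggressive, -1 = normal) gates stage 2 (+1 = knocking,
    -1 = chasing); normal episodes never reach stage 2. Returns string
    labels from {"normal", "knocking", "chasing"}.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    out = np.empty(len(X), dtype=object)
    s1 = stage1.predict(X)
    out[s1 == -1] = "normal"
    aggressive = s1 == 1
    if np.any(aggressive):
        s2 = stage2.predict(X[aggressive])
        out[aggressive] = np.where(s2 == 1, "knocking", "chasing")
    return out.astype(str)


def _round1(x: float) -> float:
    """Round half-up to 1 decimal (95.65 -> 95.7, 90.05 -> 90.1)."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def display_round(x: float) -> float:
    return _round1(x)


@dataclass(frozen=True)
class DetectionMetrics:
    """Stage-1 confusion counts and rates (aggressive = positive)."""

    TP: int
    FP: int
    TN: int
    FN: int
    ADR: float
    FPR: float
    FNR: float

    def display(self) -> dict[str, float]:
        return {
            "ADR": _round1(self.ADR),
            "FPR": _round1(self.FPR),
            "FNR": _round1(self.FNR),
        }


@dataclass(frozen=True)
class ClassMetrics:
    """Stage-2 per-class and macro precision/recall (percent)."""

    precision: dict[str, float]
    recall: dict[str, float]
    macro_precision: float
    macro_recall: float

    def display(self) -> dict[str, float]:
        d = {f"precision_{k}": _round1(v) for k, v in self.precision.items()}
        d.update({f"recall_{k}": _round1(v) for k, v in self.recall.items()})
        d["macro_precision"] = _round1(self.macro_precision)
        d["macro_recall"] = _round1(self.macro_recall)
        return d


def detection_metrics(TP: int, FP: int, TN: int, FN: int) -> DetectionMetrics:
    """ADR/FPR/FNR from detection confusion counts.

    ADR and FNR partition the aggressive episodes, so they sum to 100
    exactly; FPR is the share of normal episodes falsely flagged.
    """
    if min(TP, FP, TN, FN) < 0:
        raise ValueError("confusion counts must be non-negative")
    if TP + FN == 0:
        raise ValueError("ADR/FNR undefined: no positive examples (TP + FN = 0)")
    if FP + TN == 0:
        raise ValueError("FPR undefined: no negative examples (FP + TN = 0)")
    return DetectionMetrics(
        TP=TP,
        FP=FP,
        TN=TN,
        FN=FN,
        ADR=TP / (TP + FN) * 100.0,
        FPR=FP / (FP + TN) * 100.0,
        FNR=FN / (TP + FN) * 100.0,
    )


def classification_metrics(
    confusion: np.ndarray, classes: tuple[str, str] = ("knocking", "chasing")
) -> ClassMetrics:
    """Per-class precision/recall from a 2x2 confusion matrix.

    ``confusion[i, j]`` counts true class i predicted as class j. Each
    class is treated as positive in turn; the macro average is the
    unweighted mean of the two classes. A class never predicted gets
    precision 0 with a warning rather than an error.
    """
    cm = np.asarray(confusion)
    if cm.shape != (2, 2):
        raise ValueError(f"expected a 2x2 confusion matrix, got {cm.shape}")
    if np.any(cm.sum(axis=1) == 0):
        raise ValueError("each true class must have at least one example")
    precision: dict[str, float] = {}
    recall: dict[str, float] = {}
    for i, cls in enumerate(classes):
        tp = cm[i, i]
        fp = cm[1 - i, i]
        fn = cm[i, 1 - i]
        if tp + fp == 0:
            warnings.warn(f"class {cls!r} never predicted; precision reported as 0")
            precision[cls] = 0.0
        else:
            precision[cls] = float(tp / (tp + fp) * 100.0)
        recall[cls] = float(tp / (tp + fn) * 100.0)
    return ClassMetrics(
        precision=precision,
        recall=recall,
        macro_precision=float(np.mean(list(precision.values()))),
        macro_recall=float(np.mean(list(recall.values()))),
    )


def _stratified_oof_predictions(
    X: np.ndarray, y: np.ndarray, spec: KernelSpec, k: int, seed: int
) -> np.ndarray:
    """Out-of-fold {-1,+1} predictions from stratified k-fold CV.

    Standardization and the SVM are refit on each training fold; if the
    rarest class has fewer than k members, folding degrades to
    leave-one-out with a warning.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            f"class with {counts.min()} < {k} members; using leave-one-out"
        )
        k = len(y)
        splits = [(np.delete(np.arange(len(y)), i), np.array([i])) for i in range(len(y))]
    else:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = list(skf.split(X, y))
    pred = np.empty(len(y), dtype=int)
    for train_idx, test_idx in splits:
        model = train_svm(X[train_idx], y[train_idx], spec)
        pred[test_idx] = model.predict(X[test_idx])
    return pred


def cross_validate(
    X: np.ndarray,
    labels: np.ndarray,
    stage: int,
    spec: KernelSpec | None = None,
    k: int = 10,
    seed: int = 0,
) -> DetectionMetrics | ClassMetrics:
    """Stratified k-fold CV for one stage; metrics from pooled OOF counts.

    Stage 1 takes labels {"normal", "knocking", "chasing"} (or
    "aggressive"), scores aggressive-vs-normal and returns
    DetectionMetrics. Stage 2 takes labels {"knocking", "chasing"} and
    returns ClassMetrics. Deterministic in (X, labels, spec, k, seed).
    """
    labels = np.asarray(labels)
    if stage == 1:
        spec = spec or STAGE1_KERNEL
        y = np.where(labels == "normal", -1, 1)
        pred = _stratified_oof_predictions(X, y, spec, k, seed)
        TP = int(np.sum((y == 1) & (pred == 1)))
        FP = int(np.sum((y == -1) & (pred == 1)))
        TN = int(np.sum((y == -1) & (pred == -1)))
        FN = int(np.sum((y == 1) & (pred == -1)))
        return detection_metrics(TP, FP, TN, FN)
    if stage == 2:
        spec = spec or STAGE2_KERNEL
        valid = {"knocking", "chasing"}
        if not set(np.unique(labels)) <= valid:
            raise ValueError(f"stage-2 labels must be in {valid}")
        y = np.where(labels == "knocking", 1, -1)
        pred = _stratified_oof_predictions(X, y, spec, k, seed)
        cm = np.zeros((2, 2), dtype=int)  # rows true, cols predicted
        for yi, pi in zip(y, pred):
            cm[0 if yi == 1 else 1, 0 if pi == 1 else 1] += 1
        return classification_metrics(cm, classes=("knocking", "chasing"))
    raise ValueError(f"stage must be 1 or 2, got {stage}")
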