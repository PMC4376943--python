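"""Per-subject linear SVM classification of working-memory load.

The predictor space (2352 sliding-window features) is large relative to the
20 labelled training trials, so a linear SVM is used and its regularization
parameter C is selected per subject by repeated stratified cross-validation
(5-fold, 10 repeats) over a decade grid from 1e-5 to 10.  Ties in mean CV
accuracy resolve toward the smallest C (strongest regularization).

Features are z-scored with statistics computed from the training set only
(zero-variance features get unit scale); the fitted model is a frozen linear
rule ``sign(w·x_scaled + b)``, with decision values >= 0 mapped to the
positive class (high load by convention, so "sensitivity" is the recall of
high-load trials).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import RepeatedKFold, RepeatedStratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "C_GRID",
    "CvPlan",
    "ClassifierModel",
    "EvalScore",
    "select_C",
    "train",
    "classify_trial",
    "evaluate",
    "save_model",
    "load_model",
]

#: Default regularization grid: seven decades from 1e-5 to 10.
C_GRID = tuple(10.0**k for k in range(-5, 2))


@dataclass(frozen=True)
class CvPlan:
    folds: int = 5
    repeats: int = 10
    stratified: bool = True
    seed: int = 0


@dataclass
class ClassifierModel:
    """Frozen linear decision rule with its training-set scaler."""

    weights: np.ndarray
    bias: float
    C: float
    center: np.ndarray
    scale: np.ndarray
    positive_class: str = "high"
    negative_class: str = "low"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.scale = np.asarray(self.scale, dtype=float)
        if not (len(self.weights) == len(self.center) == len(self.scale)):
            raise ValueError("weights/center/scale lengths differ")
        if (self.scale <= 0).any():
            raise ValueError("scale entries must be positive")

    @property
    def n_features(self) -> int:
        return len(self.weights)

    def decision_function(self, fv: np.ndarray) -> float:
        fv = np.asarray(fv, dtype=float)
        if fv.shape != self.weights.shape:
            raise ValueError(
                f"feature vector length {fv.shape} != model length {self.weights.shape}"
            )
        return float(self.weights @ ((fv - self.center) / self.scale) + self.bias)


@dataclass
class EvalScore:
    accuracy: float
    sensitivity: float  # recall of the positive (high-load) class
    specificity: float  # recall of the negative (low-load) class
    predictions: tuple = field(default_factory=tuple)


def _fit_scaler(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return center, scale


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training labels must contain both classes")


def select_C(
    X: np.ndarray,
    y: np.ndarray,
    grid=C_GRID,
    plan: CvPlan | None = None,
) -> tuple[float, pd.DataFrame]:
    """Choose C by mean accuracy over repeated (stratified) k-fold CV.

    Returns the winning C and the full (C, mean_cv_accuracy) table.  The
    argmax is taken over all fold-fits (folds x repeats); exact ties go to
    the smallest C.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    plan = plan or CvPlan()
    if plan.stratified:
        cv = RepeatedStratifiedKFold(
            n_splits=plan.folds, n_repeats=plan.repeats, random_state=plan.seed
        )
    else:
        cv = RepeatedKFold(
            n_splits=plan.folds, n_repeats=plan.repeats, random_state=plan.seed
        )
    splits = list(cv.split(X, y))

    rows = []
    for C in grid:
        accs = []
        for tr, va in splits:
            center, scale = _fit_scaler(X[tr])
            svc = SVC(kernel="linear", C=C)
            svc.fit((X[tr] - center) / scale, y[tr])
            accs.append(float(np.mean(svc.predict((X[va] - center) / scale) == y[va])))
        rows.append((float(C), float(np.mean(accs))))
    table = pd.DataFrame(rows, columns=["C", "mean_cv_accuracy"])

    best_c, best_acc = None, -np.inf
    for C, acc in sorted(rows):  # ascending C: strict improvement required
        if acc > best_acc + 1e-12:
            best_c, best_acc = C, acc
    return best_c, table


def train(
    X: np.ndarray, y: np.ndarray, C: float, positive_class: str = "high"
) -> ClassifierModel:
    """Fit the linear SVM at a fixed C; scaler statistics come from X only."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    classes = sorted(np.unique(y))
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} absent from labels")
    negative_class = next(c for c in classes if c != positive_class)

    center, scale = _fit_scaler(X)
    svc = SVC(kernel="linear", C=C)
    svc.fit((X - center) / scale, y)
    w = svc.coef_[0].copy()
    b = float(svc.intercept_[0])
    # sklearn's decision function is positive for classes_[1]
    if svc.classes_[1] != positive_class:
        w, b = -w, -b
    return ClassifierModel(
        weights=w,
        bias=b,
        C=float(C),
        center=center,
        scale=scale,
        positive_class=str(positive_class),
        negative_class=str(negative_class),
    )


def classify_trial(model: ClassifierModel, fv: np.ndarray) -> str:
    """Label one trial; a decision value of exactly 0 maps to the positive class."""
    d = model.decision_function(fv)
    return model.positive_class if d >= 0 else model.negative_class


def evaluate(model: ClassifierModel, X_test: np.ndarray, y_test: np.ndarray) -> EvalScore:
    """Accuracy plus recall of the positive (sensitivity) and negative
    (specificity) classes on a held-out set."""
    X_test = np.asarray(X_test, dtype=float)
    y_test = np.asarray(y_test)
    if len(X_test) == 0:
        raise ValueError("empty test set")
    preds = np.array([classify_trial(model, x) for x in X_test])
    pos, neg = model.positive_class, model.negative_class
    accuracy = float(np.mean(preds == y_test))
    pos_mask = y_test == pos
    neg_mask = y_test == neg
    sensitivity = float(np.mean(preds[pos_mask] == pos)) if pos_mask.any() else float("nan")
    specificity = float(np.mean(preds[neg_mask] == neg)) if neg_mask.any() else float("nan")
    return EvalScore(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        predictions=tuple(preds.tolist()),
    )


def save_model(model: ClassifierModel, path) -> None:
    """Serialize the model to a documented JSON file."""
    payload = {
        "weights": model.weights.tolist(),
        "bias": model.bias,
        "C": model.C,
        "center": model.center.tolist(),
        "scale": model.scale.tolist(),
        "positive_class": model.positive_class,
        "negative_class": model.negative_class,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> ClassifierModel:
    with open(path) as fh:
        payload = json.load(fh)
    return ClassifierModel(
        weights=np.asarray(payload["weights"]),
        bias=float(payload["bias"]),
        C=float(payload["C"]),
        center=np.asarray(payload["center"]),
        scale=np.asarray(payload["scale"]),
        positive_class=payload["positive_class"],
        negative_class=payload["negative_class"],
    )
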