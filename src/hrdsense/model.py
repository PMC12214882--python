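"""Linear-kernel SVM HRD classifier.

Training pipeline: per-feature z-scoring (StandardScaler), regularization
strength C chosen from a grid by stratified 10-fold cross-validation
maximizing mean ROC AUC, final refit on all training data, and Platt-style
sigmoid calibration fitted to cross-validated decision values so that the
model emits HRD probabilities. Samples with probability >= 0.50 are called
HRD at the default operating point.

The fitted model is a plain parameter set (scaler means/sds, weights, bias,
sigmoid slope/intercept); prediction is implemented directly from those
parameters, so a serialized model round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureVector
from .schemas import FEATURE_ORDER

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
DEFAULT_THRESHOLD = 0.50


@dataclass(frozen=True)
class TrainedModel:
    """All parameters needed to reproduce predictions exactly."""

    cancer_type: str
    assay: str
    feature_order: tuple[str, ...]
    scaler_means: tuple[float, ...]
    scaler_sds: tuple[float, ...]
    svm_weights: tuple[float, ...]
    svm_bias: float
    calibration_slope: float
    calibration_intercept: float
    regularization_c: float
    threshold: float
    training_seed: int
    training_auc: float
    cv_mean_weights: tuple[float, ...]
    cv_mean_auc: float

    def to_json(self) -> str:
        payload = {"format_version": MODEL_FORMAT_VERSION}
        payload.update(dataclasses.asdict(self))
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        payload = json.loads(text)
        version = payload.pop("format_version", None)
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version!r}")
        for key in (
            "feature_order",
            "scaler_means",
            "scaler_sds",
            "svm_weights",
            "cv_mean_weights",
        ):
            payload[key] = tuple(payload[key])
        return cls(**payload)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


@dataclass(frozen=True)
class EvaluationReport:
    auc: Optional[float]
    sensitivity: float
    precision: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int


def _platt_fit(decision_values: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit sigmoid p = 1 / (1 + exp(a*f + b)) by penalized max likelihood.

    Uses Platt's smoothed targets to avoid degenerate fits on separable data.
    """
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(y, dtype=int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def objective(params):
        a, b = params
        z = a * f + b
        # log(1 + exp(z)) computed stably
        log1pexp = np.logaddexp(0.0, z)
        # p = sigmoid(-z); NLL = sum t*z + log(1+exp(-z)) rearranged:
        nll = np.sum(t * z + log1pexp - z)
        p = 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))
        grad_z = t - p
        return nll, np.array([np.sum(grad_z * f), np.sum(grad_z)])

    result = minimize(
        objective,
        x0=np.array([-1.0, 0.0]),
        jac=True,
        method="L-BFGS-B",
    )
    a, b = result.x
    return float(a), float(b)


def _matrix(features: Sequence[FeatureVector]) -> np.ndarray:
    return np.array([fv.as_array() for fv in features], dtype=float)


def _label_vector(
    features: Sequence[FeatureVector], labels: Mapping[str, str]
) -> np.ndarray:
    return np.array([1 if labels[fv.sample_id] == "HRD" else 0 for fv in features])


def fit(
    features: Sequence[FeatureVector],
    labels: Mapping[str, str],
    cancer_type: str = "breast",
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    n_folds: int = 10,
    seed: int = 0,
    threshold: float = DEFAULT_THRESHOLD,
) -> TrainedModel:
    """Train the six-feature linear SVM classifier.

    Deterministic given ``seed``. Raises on single-class input; the fold
    count is reduced with a warning when a class has fewer samples than
    folds.
    """
    assays = {fv.assay for fv in features}
    if len(assays) != 1:
        raise ValueError(f"features mix assays {sorted(assays)}; train per assay")
    assay = assays.pop()

    X = _matrix(features)
    y = _label_vector(features, labels)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("training data must contain both HRD and HRP samples")
    if min(n_pos, n_neg) < 2:
        raise ValueError("need at least 2 samples per class")
    if min(n_pos, n_neg) < n_folds:
        n_folds = min(n_pos, n_neg)
        logger.warning("reducing CV folds to %d (smallest class size)", n_folds)

    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)

    mean_aucs = []
    for c in c_grid:
        aucs = []
        for train_idx, val_idx in skf.split(Z, y):
            svm = SVC(kernel="linear", C=c).fit(Z[train_idx], y[train_idx])
            scores = svm.decision_function(Z[val_idx])
            if len(np.unique(y[val_idx])) < 2:
                continue
            aucs.append(roc_auc_score(y[val_idx], scores))
        mean_aucs.append(float(np.mean(aucs)))
    best_idx = int(np.argmax(mean_aucs))  # ties resolve to the smaller C
    best_c = float(c_grid[best_idx])

    fold_weights = []
    for train_idx, _ in skf.split(Z, y):
        svm = SVC(kernel="linear", C=best_c).fit(Z[train_idx], y[train_idx])
        fold_weights.append(svm.coef_[0])
    cv_mean_weights = np.mean(fold_weights, axis=0)

    final = SVC(kernel="linear", C=best_c).fit(Z, y)
    weights = final.coef_[0]
    bias = float(final.intercept_[0])

    cv_decisions = cross_val_predict(
        SVC(kernel="linear", C=best_c), Z, y, cv=skf, method="decision_function"
    )
    slope, intercept = _platt_fit(cv_decisions, y)

    model = TrainedModel(
        cancer_type=cancer_type,
        assay=assay,
        feature_order=tuple(FEATURE_ORDER),
        scaler_means=tuple(float(v) for v in scaler.mean_),
        scaler_sds=tuple(float(v) for v in scaler.scale_),
        svm_weights=tuple(float(v) for v in weights),
        svm_bias=bias,
        calibration_slope=slope,
        calibration_intercept=intercept,
        regularization_c=best_c,
        threshold=threshold,
        training_seed=seed,
        training_auc=0.0,
        cv_mean_weights=tuple(float(v) for v in cv_mean_weights),
        cv_mean_auc=float(mean_aucs[best_idx]),
    )
    training_probs = predict_proba(model, features, check_assay=False)
    training_auc = float(roc_auc_score(y, training_probs))
    return dataclasses.replace(model, training_auc=training_auc)


def decision_values(model: TrainedModel, features: Sequence[FeatureVector]) -> np.ndarray:
    X = _matrix(features)
    means = np.array(model.scaler_means)
    sds = np.array(model.scaler_sds)
    Z = (X - means) / sds
    return Z @ np.array(model.svm_weights) + model.svm_bias


def predict_proba(
    model: TrainedModel,
    features: Sequence[FeatureVector],
    check_assay: bool = True,
) -> np.ndarray:
    """Calibrated HRD probability for each sample."""
    if check_assay:
        assays = {fv.assay for fv in features}
        if assays != {model.assay}:
            raise ValueError(
                f"model was trained on {model.assay} but features are "
                f"{sorted(assays)}; pass check_assay=False to override"
            )
    f = decision_values(model, features)
    z = model.calibration_slope * f + model.calibration_intercept
    return 1.0 / (1.0 + np.exp(np.clip(z, -500, 500)))


def classify(
    probabilities: Sequence[float], threshold: float = DEFAULT_THRESHOLD
) -> list[str]:
    """HRD call per sample: HRD iff probability >= threshold."""
    return ["HRD" if p >= threshold else "HRP" for p in probabilities]


def evaluate(
    predicted: Sequence[str],
    probabilities: Sequence[float],
    truth: Sequence[str],
) -> EvaluationReport:
    """Confusion-matrix metrics plus rank AUC against ground truth."""
    if not (len(predicted) == len(probabilities) == len(truth)):
        raise ValueError("predicted, probabilities and truth must align")
    y = np.array([1 if t == "HRD" else 0 for t in truth])
    calls = np.array([1 if p == "HRD" else 0 for p in predicted])
    tp = int(np.sum((calls == 1) & (y == 1)))
    fp = int(np.sum((calls == 1) & (y == 0)))
    tn = int(np.sum((calls == 0) & (y == 0)))
    fn = int(np.sum((calls == 0) & (y == 1)))
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity
        else 0.0
    )
    auc = None
    if len(np.unique(y)) == 2:
        auc = float(roc_auc_score(y, np.asarray(probabilities, dtype=float)))
    return EvaluationReport(
        auc=auc,
        sensitivity=sensitivity,
        precision=precision,
        f1=f1,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )
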