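"""RBF-SVM interface classifier, repeated-split evaluation, and metrics.

The classifier is a support vector machine with a radial basis function
kernel, fitted on standardised features with class weights inverse to the
class frequencies (the training design fixes a 1:5 native:non-native
ratio). Probabilities come from Platt scaling fitted on the training data.

Evaluation follows a repeated random-split protocol: 100 trials, each a
seeded stratified 80/20 train/test split, with the mean and SD of test
accuracy and AUC reported across trials, and the confusion counts recorded
at every probability threshold 0.50, 0.55, ..., 0.95 (fractional mean
counts over trials are therefore meaningful).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureSchema, FeatureVector, default_schema

__all__ = [
    "ScalingStats",
    "SvmModel",
    "ConfusionCounts",
    "TrialResult",
    "CrossValidationSummary",
    "train",
    "predict_probability",
    "cross_validate",
    "confusion_metrics",
    "roc_auc",
    "threshold_sweep",
    "DEFAULT_THRESHOLDS",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

DEFAULT_C = 10.0
DEFAULT_THRESHOLDS: tuple[float, ...] = tuple(
    round(0.50 + 0.05 * i, 2) for i in range(10))


@dataclass(frozen=True)
class ScalingStats:
    """Per-feature location/scale learned from training data only."""

    mean: np.ndarray
    scale: np.ndarray   # constant features get scale 1

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


@dataclass
class SvmModel:
    """Fitted, Platt-calibrated RBF-SVM with its scaler and schema version."""

    svc: CalibratedClassifierCV
    scaling: ScalingStats
    schema_version: str
    n_features: int

    def predict_proba_native(self, X: np.ndarray) -> np.ndarray:
        Xs = self.scaling.transform(np.atleast_2d(X))
        native_col = list(self.svc.classes_).index(1)
        return self.svc.predict_proba(Xs)[:, native_col]


def _as_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        y = np.array([1 if str(v) == "native" else 0 for v in y])
    return X, y.astype(int)


def train(X: np.ndarray, y: np.ndarray,
          C: float = DEFAULT_C, gamma: float | str | None = None,
          schema: FeatureSchema | None = None,
          seed: int = 0) -> SvmModel:
    """Fit the RBF-SVM on standardised features.

    ``gamma`` defaults to 1/n_features; class weights are inverse to class
    frequency ('balanced'), mirroring the fixed 1:5 imbalance without
    oversampling. Probabilities come from Platt (sigmoid) calibration
    fitted on stratified folds of the training data only.
    """
    X, y = _as_xy(X, y)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    counts = np.bincount(y)
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    scaler = StandardScaler().fit(X)
    scale = np.where(scaler.scale_ == 0, 1.0, scaler.scale_)
    stats = ScalingStats(scaler.mean_, scale)
    base = SVC(kernel="rbf", C=C,
               gamma=("auto" if gamma is None else gamma),
               class_weight="balanced")
    cv = int(min(5, counts.min()))  # every calibration fold needs both classes
    svc = CalibratedClassifierCV(base, method="sigmoid", cv=cv,
                                 ensemble=False)
    svc.fit(stats.transform(X), y)
    schema = schema or default_schema()
    return SvmModel(svc, stats, schema.version, X.shape[1])


def predict_probability(model: SvmModel,
                        x: FeatureVector | np.ndarray) -> np.ndarray:
    """P(native) for one vector or a matrix of vectors, in [0, 1].

    A :class:`FeatureVector` must carry the schema version the model was
    trained with; raw arrays must match the feature count.
    """
    if isinstance(x, FeatureVector):
        if x.schema.version != model.schema_version:
            raise ValueError(
                f"schema version mismatch: model {model.schema_version!r} "
                f"vs vector {x.schema.version!r}")
        x = x.values
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.n_features:
        raise ValueError(f"expected {model.n_features} features, "
                         f"got {x.shape[1]}")
    return model.predict_proba_native(x)


# ---------------------------------------------------------------------------
# Confusion counts and scalar metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class ConfusionCounts:
    """TP/TN/FP/FN at one probability threshold; fractional means allowed."""

    tp: float
    tn: float
    fp: float
    fn: float
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def confusion_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy (%), TPR, TNR, NPV, precision, F1 and MCC from raw counts.

    All 0/0 ratios are 0 by convention, so degenerate slices (e.g. no
    predicted positives) stay defined.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    total = tp + tn + fp + fn
    tpr = _safe_div(tp, tp + fn)
    tnr = _safe_div(tn, tn + fp)
    npv = _safe_div(tn, tn + fn)
    precision = _safe_div(tp, tp + fp)
    f1 = _safe_div(2.0 * precision * tpr, precision + tpr)
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, denom)
    return {
        "accuracy": _safe_div(tp + tn, total) * 100.0,
        "TPR": tpr, "TNR": tnr, "NPV": npv,
        "precision": precision, "F1": f1, "MCC": mcc,
    }


def roc_auc(scores: Sequence[float], labels: Sequence[int]
            ) -> tuple[float, np.ndarray, np.ndarray]:
    """Trapezoidal ROC AUC with tied scores grouped; returns (AUC, FPR, TPR)."""
    scores = np.asarray(scores, dtype=float)
    _, y = _as_xy(np.zeros((len(scores), 1)), np.asarray(labels))
    if len(np.unique(y)) < 2:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = _sk_roc_curve(y, scores)
    return float(_sk_auc(fpr, tpr)), fpr, tpr


def _count_at(scores: np.ndarray, y: np.ndarray,
              threshold: float) -> ConfusionCounts:
    pred = scores >= threshold
    return ConfusionCounts(
        tp=float(np.sum(pred & (y == 1))),
        tn=float(np.sum(~pred & (y == 0))),
        fp=float(np.sum(pred & (y == 0))),
        fn=float(np.sum(~pred & (y == 1))),
        threshold=threshold,
    )


def threshold_sweep(scores: Sequence[float], labels: Sequence[int],
                    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
                    ) -> pd.DataFrame:
    """Confusion counts + metrics at each probability threshold.

    One row per threshold with columns threshold, TP, TN, FP, FN, accuracy,
    TPR, TNR, NPV, precision, F1, MCC (the benchmark-table layout).
    """
    scores = np.asarray(scores, dtype=float)
    _, y = _as_xy(np.zeros((len(scores), 1)), np.asarray(labels))
    rows = []
    for t in thresholds:
        c = _count_at(scores, y, t)
        m = confusion_metrics(c)
        rows.append({"threshold": t, "TP": c.tp, "TN": c.tn,
                     "FP": c.fp, "FN": c.fn, **m})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Repeated-split evaluation
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class TrialResult:
    """One train/test trial: held-out accuracy, AUC and per-threshold counts."""

    trial: int
    accuracy: float          # percent, at threshold 0.5
    auc: float
    counts: list[ConfusionCounts]


@dataclass(slots=True)
class CrossValidationSummary:
    """Mean +/- SD over trials plus the mean confusion table per threshold."""

    mean_accuracy: float
    sd_accuracy: float
    mean_auc: float
    sd_auc: float
    trials: list[TrialResult]

    def mean_threshold_table(self) -> pd.DataFrame:
        rows = []
        n_thresh = len(self.trials[0].counts)
        for k in range(n_thresh):
            cs = [t.counts[k] for t in self.trials]
            mean_c = ConfusionCounts(
                tp=float(np.mean([c.tp for c in cs])),
                tn=float(np.mean([c.tn for c in cs])),
                fp=float(np.mean([c.fp for c in cs])),
                fn=float(np.mean([c.fn for c in cs])),
                threshold=cs[0].threshold)
            rows.append({"threshold": mean_c.threshold, "TP": mean_c.tp,
                         "TN": mean_c.tn, "FP": mean_c.fp, "FN": mean_c.fn,
                         **confusion_metrics(mean_c)})
        return pd.DataFrame(rows)


def cross_validate(dataset, n_trials: int = 100, train_frac: float = 0.8,
                   seed: int = 0, C: float = DEFAULT_C,
                   gamma: float | str | None = None,
                   thresholds: Sequence[float] = DEFAULT_THRESHOLDS
                   ) -> CrossValidationSummary:
    """Repeated stratified 80/20 split evaluation (100 trials by default).

    ``dataset`` is a :class:`~dockface.dataset.LabeledSet` or an (X, y)
    tuple. Each trial derives its split and SVM seed from the master seed
    (seed + trial index), trains on the 80% and evaluates on the held-out
    20%; the summary reports the mean and SD of test accuracy (percent)
    and AUC. A test split that comes out single-class is resampled; if the
    class counts make a two-class test split impossible (e.g. a single
    12-sample 1:5 block), the trial's AUC is undefined (NaN, excluded
    from the summary mean) and a warning is logged once.
    """
    if hasattr(dataset, "matrices"):
        X, y = dataset.matrices()
    else:
        X, y = dataset
    X, y = _as_xy(X, y)
    if len(np.unique(y)) < 2:
        raise ValueError("dataset must contain both classes")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")

    trials: list[TrialResult] = []
    for t in range(n_trials):
        trial_seed = int(seed) + t
        for resample in range(20):
            splitter = StratifiedShuffleSplit(
                n_splits=1, train_size=train_frac,
                random_state=trial_seed + 1_000_003 * resample)
            train_idx, test_idx = next(splitter.split(X, y))
            if len(np.unique(y[test_idx])) == 2 and \
                    np.bincount(y[train_idx]).min() >= 2:
                break
        model = train(X[train_idx], y[train_idx], C=C, gamma=gamma,
                      seed=trial_seed)
        p = model.predict_proba_native(X[test_idx])
        y_test = y[test_idx]
        acc = float(np.mean((p >= 0.5).astype(int) == y_test)) * 100.0
        if len(np.unique(y_test)) == 2:
            auc_val, _, _ = roc_auc(p, y_test)
        else:
            auc_val = float("nan")
        counts = [_count_at(p, y_test, th) for th in thresholds]
        trials.append(TrialResult(t, acc, auc_val, counts))

    accs = np.array([t.accuracy for t in trials])
    aucs = np.array([t.auc for t in trials])
    n_bad = int(np.isnan(aucs).sum())
    if n_bad:
        logger.warning("%d/%d trials had a single-class test split; their "
                       "AUC is undefined and excluded from the summary",
                       n_bad, n_trials)
    with np.errstate(invalid="ignore"):
        mean_auc = float(np.nanmean(aucs)) if n_bad < n_trials else \
            float("nan")
        sd_auc = float(np.nanstd(aucs, ddof=1)) \
            if n_trials - n_bad > 1 else 0.0
    return CrossValidationSummary(float(accs.mean()),
                                  float(accs.std(ddof=1))
                                  if n_trials > 1 else 0.0,
                                  mean_auc, sd_auc, trials)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: SvmModel, path: str | Path) -> None:
    """Persist the model as one self-describing archive."""
    joblib.dump({"schema_version": model.schema_version,
                 "n_features": model.n_features,
                 "scaling_mean": model.scaling.mean,
                 "scaling_scale": model.scaling.scale,
                 "svc": model.svc}, path)


def load_model(path: str | Path) -> SvmModel:
    obj = joblib.load(path)
    return SvmModel(obj["svc"],
                    ScalingStats(obj["scaling_mean"], obj["scaling_scale"]),
                    obj["schema_version"], obj["n_features"])
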