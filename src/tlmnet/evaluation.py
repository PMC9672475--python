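"""Model registry, repeated stratified cross-validation, and metrics.

The evaluation protocol is 5x repeated stratified 10-fold cross-validation.
Inside every fold the scaler, the naive-Bayes feature selection (capping
the feature count at the number of training samples) and the classifier
are fitted on the training rows only; the held-out fold is scored with the
Matthews correlation coefficient (MCC) and ROC AUC, and the median across
all folds and repeats is the headline summary.

Learners come configured from scikit-learn / XGBoost; the registry pins
the hyperparameter overrides used throughout (everything else at library
defaults).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.linear_model import LogisticRegressionCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC, LinearSVC
from xgboost import XGBClassifier

from .features import (
    FeatureDescriptor,
    FeatureTable,
    labels_to_binary,
    select_top_features,
    standardize,
)
from .types import PhenotypeLabels


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)); when any
    denominator factor is zero the score is defined as 0.
    """
    num = c.tp * c.tn - c.fp * c.fn
    factors = [c.tp + c.fn, c.tp + c.fp, c.tn + c.fp, c.tn + c.fn]
    if any(f == 0 for f in factors):
        return 0.0
    return num / math.sqrt(math.prod(factors))


def confusion_from_predictions(
    y_true: np.ndarray, y_pred: np.ndarray
) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def roc_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Area under the ROC curve (ties count one half)."""
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC AUC requires both classes")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


MODEL_KEYS = ("XGB", "RF", "ET", "PSVC", "LSVC", "LRCV")

# Hyperparameter overrides per model; everything else stays at the
# backing library's defaults.
_MODEL_OVERRIDES: dict[str, dict] = {
    "XGB": dict(n_estimators=500, max_depth=3, eval_metric="logloss",
                learning_rate=0.1),
    "RF": dict(n_estimators=500, criterion="entropy", max_features=0.25),
    "ET": dict(n_estimators=1000, max_features="log2", criterion="entropy"),
    "PSVC": dict(C=0.01, gamma=0.1, degree=3, coef0=10, kernel="poly"),
    "LSVC": dict(max_iter=100_000),
    "LRCV": dict(max_iter=10_000),
}


@dataclass(frozen=True)
class ModelSpec:
    model_key: str
    class_weight: str | None = None  # None or "balanced"

    def __post_init__(self) -> None:
        if self.model_key not in MODEL_KEYS:
            raise ValueError(f"unknown model key {self.model_key!r}")
        if self.class_weight not in (None, "balanced"):
            raise ValueError("class_weight must be None or 'balanced'")

    @property
    def hyperparameters(self) -> dict:
        return dict(_MODEL_OVERRIDES[self.model_key])


def build_model(spec: ModelSpec, seed: int | None = None):
    """Instantiate the configured classifier for a ModelSpec."""
    params = spec.hyperparameters
    if spec.model_key == "XGB":
        if spec.class_weight is not None:
            raise ValueError("XGB has no class_weight parameter")
        return XGBClassifier(random_state=seed, **params)
    if spec.class_weight is not None:
        params["class_weight"] = spec.class_weight
    if spec.model_key == "RF":
        return RandomForestClassifier(random_state=seed, **params)
    if spec.model_key == "ET":
        return ExtraTreesClassifier(random_state=seed, **params)
    if spec.model_key == "PSVC":
        return SVC(random_state=seed, **params)
    if spec.model_key == "LSVC":
        return LinearSVC(random_state=seed, **params)
    return LogisticRegressionCV(random_state=seed, **params)


def decision_scores(model, x: np.ndarray) -> np.ndarray:
    """Continuous ranking scores for AUC: positive-class probability when
    available, else the decision function."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return model.decision_function(x)


@dataclass(frozen=True)
class CVRecord:
    repeat: int
    fold: int
    model_key: str
    feature_set_id: str
    metric: str  # MCC | AUC
    value: float
    seed: int


@dataclass
class CVRecordSet:
    records: list[CVRecord] = field(default_factory=list)
    folds: list[tuple[int, int, np.ndarray, np.ndarray]] = field(default_factory=list)
    heldout_probabilities: dict[tuple[int, int], tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def values(self, metric: str, **filters: str) -> np.ndarray:
        out = [
            r.value
            for r in self.records
            if r.metric == metric
            and all(getattr(r, k) == v for k, v in filters.items())
        ]
        return np.array(out)

    def extend(self, other: "CVRecordSet") -> None:
        self.records.extend(other.records)
        self.folds.extend(other.folds)


def fit_fold_pipeline(
    x_table: FeatureTable,
    y: np.ndarray,
    train_idx: np.ndarray,
    model_spec: ModelSpec,
    seed: int | None,
    instrument: Callable[[str, np.ndarray], None] | None = None,
):
    """Fit scaler -> feature selection -> classifier on training rows only.

    Returns (model, transform) where transform maps any FeatureTable-sized
    value matrix onto the standardized, selected feature columns.
    """
    train_samples = [x_table.samples[i] for i in train_idx]
    train_table = x_table.restrict_samples(train_samples)
    if instrument is not None:
        instrument("scaler_fit", train_idx)
    scaler, train_std = standardize(train_table, train_table)
    k = len(train_idx)  # feature count never exceeds the training sample count
    if instrument is not None:
        instrument("selection_fit", train_idx)
    selected = select_top_features(train_std, y[train_idx], k=k)
    sel_cols = [x_table.features.index(f) for f in selected]
    mean = scaler.mean[sel_cols]
    sd = scaler.sd[sel_cols]

    def transform(values: np.ndarray) -> np.ndarray:
        return (values[:, sel_cols] - mean) / sd

    model = build_model(model_spec, seed=seed)
    if instrument is not None:
        instrument("model_fit", train_idx)
    model.fit(transform(x_table.values[train_idx]), y[train_idx])
    return model, transform, selected


def repeated_stratified_cv(
    x_table: FeatureTable,
    y: PhenotypeLabels | np.ndarray,
    model_spec: ModelSpec,
    repeats: int = 5,
    folds: int = 10,
    seed: int = 0,
    feature_set_id: str = "",
    instrument: Callable[[int, int, str, np.ndarray], None] | None = None,
    collect_probabilities: bool = False,
) -> CVRecordSet:
    """Repeated stratified k-fold cross-validation with in-fold scaling and
    feature selection.

    Each repeat reshuffles with a seed derived deterministically from the
    master seed (master + repeat index), so an identical master seed yields
    an identical record set.
    """
    if isinstance(y, PhenotypeLabels):
        y_bin = labels_to_binary(y, x_table.samples)
    else:
        y_bin = np.asarray(y).astype(int)
    class_counts = np.bincount(y_bin, minlength=2)
    if class_counts.min() < folds:
        raise ValueError(
            f"smallest class has {class_counts.min()} members; "
            f"cannot stratify into {folds} folds"
        )
    result = CVRecordSet()
    for repeat in range(repeats):
        repeat_seed = seed + repeat
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=repeat_seed)
        for fold, (train_idx, test_idx) in enumerate(
            splitter.split(x_table.values, y_bin)
        ):
            stage_cb = (
                (lambda stage, idx, r=repeat, f=fold: instrument(r, f, stage, idx))
                if instrument is not None
                else None
            )
            model, transform, _ = fit_fold_pipeline(
                x_table, y_bin, train_idx, model_spec, repeat_seed, stage_cb
            )
            x_test = transform(x_table.values[test_idx])
            y_pred = np.asarray(model.predict(x_test)).astype(int)
            scores = decision_scores(model, x_test)
            fold_mcc = mcc(confusion_from_predictions(y_bin[test_idx], y_pred))
            fold_auc = roc_auc(scores, y_bin[test_idx])
            for metric, value in (("MCC", fold_mcc), ("AUC", fold_auc)):
                result.records.append(
                    CVRecord(
                        repeat=repeat,
                        fold=fold,
                        model_key=model_spec.model_key,
                        feature_set_id=feature_set_id,
                        metric=metric,
                        value=float(value),
                        seed=seed,
                    )
                )
            result.folds.append((repeat, fold, train_idx.copy(), test_idx.copy()))
            if collect_probabilities:
                result.heldout_probabilities[(repeat, fold)] = (
                    test_idx.copy(),
                    scores.copy(),
                    y_bin[test_idx].copy(),
                )
    return result


def aggregate(
    records: CVRecordSet | pd.DataFrame,
    by: Sequence[str],
    stat: str = "median",
) -> pd.DataFrame:
    """Group CV records and summarize ``value`` (median/mean/sd)."""
    frame = records.to_frame() if isinstance(records, CVRecordSet) else records
    if frame.empty:
        raise ValueError("no records to aggregate")
    agg = {"median": "median", "mean": "mean", "sd": "std"}[stat]
    out = frame.groupby(list(by))["value"].agg(agg).reset_index()
    return out.rename(columns={"value": stat})


def compare_distributions(
    x: Sequence[float], y: Sequence[float], method: str = "asymptotic"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    The default asymptotic method applies the normal approximation with
    tie and continuity corrections; ``method='exact'`` enumerates the
    exact null distribution (no ties, small samples).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = mannwhitneyu(x, y, alternative="two-sided", use_continuity=True, method=method)
    return float(res.statistic), float(res.pvalue)


def permutation_importance(
    model,
    x_heldout: np.ndarray,
    y_heldout: np.ndarray,
    n_repeats: int = 5,
    seed: int | None = None,
) -> np.ndarray:
    """Per-feature drop in held-out accuracy when the feature column is
    shuffled, averaged over ``n_repeats`` shuffles."""
    if x_heldout.shape[1] != getattr(model, "n_features_in_", x_heldout.shape[1]):
        raise ValueError("feature count mismatch between model and data")
    res = _sk_permutation_importance(
        model,
        x_heldout,
        y_heldout,
        n_repeats=n_repeats,
        random_state=seed,
        scoring="accuracy",
    )
    return np.asarray(res.importances_mean)


def top_mean_abs_coefficients(
    per_run_coefficients: list[dict[FeatureDescriptor, float]],
    k: int = 15,
) -> list[tuple[FeatureDescriptor, float]]:
    """Features with the highest mean |coefficient| across runs.

    Only features selected in every run are eligible; returns up to k
    (feature, mean |coef|) pairs sorted by decreasing magnitude.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not per_run_coefficients:
        raise ValueError("no coefficient vectors given")
    eligible = set(per_run_coefficients[0])
    for coeffs in per_run_coefficients[1:]:
        eligible &= set(coeffs)
    means = {
        f: float(np.mean([abs(c[f]) for c in per_run_coefficients])) for f in eligible
    }
    ranked = sorted(means.items(), key=lambda kv: (-kv[1], kv[0].set_id))
    return ranked[:k]
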