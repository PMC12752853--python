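"""SVM classification of spectrum features, metrics, and a threshold rule.

Evaluation protocol: stratified k-fold outer cross-validation; inside each
training fold a pipeline (median imputation -> optional standardization ->
RBF-kernel SVM) is selected by an inner 3-fold grid search over a
log-spaced (C, gamma) grid.  Outer-fold predictions are pooled into one
confusion matrix and one ROC.  All preprocessing statistics are fit on
training folds only.

The threshold rule is a one-dimensional alternative: the midpoint between
the largest pathological and smallest healthy Hölder exponent of the first
mode; a value strictly below it votes malignant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.impute import SimpleImputer
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "SvmConfig",
    "ConfusionCounts",
    "MetricsReport",
    "ThresholdRule",
    "compute_metrics",
    "roc_auc",
    "cross_validate",
    "decision_threshold",
    "classify_by_threshold",
]


@dataclass(frozen=True)
class SvmConfig:
    """RBF-kernel SVM with the grid-search ranges of the source protocol."""

    c_range: tuple[float, float] = (0.5, 1156666.0)
    gamma_range: tuple[float, float] = (0.0722, 16.0)
    grid_points_per_axis: int = 8
    cv_folds: int = 5
    seed: int = 0
    scaling: str = "standardize"

    def __post_init__(self) -> None:
        if not (0 < self.c_range[0] < self.c_range[1]):
            raise ValueError("c_range must satisfy 0 < low < high")
        if not (0 < self.gamma_range[0] < self.gamma_range[1]):
            raise ValueError("gamma_range must satisfy 0 < low < high")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.scaling not in ("standardize", "none"):
            raise ValueError("scaling must be 'standardize' or 'none'")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    f1: float | None
    confusion: ConfusionCounts
    auc: float | None = None
    roc_points: np.ndarray | None = None  # (n, 2) columns (fpr, tpr)
    details: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ThresholdRule:
    threshold: float
    feature: tuple[str, str] = ("bimf_1", "alpha0")
    direction: str = "below => positive"

    @property
    def column(self) -> str:
        return f"{self.feature[0]}_{self.feature[1]}"


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(confusion: ConfusionCounts) -> MetricsReport:
    """Confusion-matrix metric suite; 0/0 cases reported as None, never 0.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    precision = TP/(TP+FP), accuracy = (TP+TN)/total,
    F1 = 2 * precision * sensitivity / (precision + sensitivity).
    """
    c = confusion
    if c.total == 0:
        raise ValueError("empty confusion matrix")
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    prec = _ratio(c.tp, c.tp + c.fp)
    acc = (c.tp + c.tn) / c.total
    if prec is None or sens is None or (prec + sens) == 0:
        f1 = None
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricsReport(
        accuracy=acc, sensitivity=sens, specificity=spec, precision=prec,
        f1=f1, confusion=c,
    )


def roc_auc(scores, labels) -> tuple[float, np.ndarray]:
    """Empirical ROC and its area (trapezoidal; tied scores mid-ranked)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute an ROC")
    auc = float(roc_auc_score(y, s))
    fpr, tpr, _ = roc_curve(y, s)
    return auc, np.column_stack([fpr, tpr])


# ---------------------------------------------------------------------------
# cross-validated SVM
# ---------------------------------------------------------------------------

def _feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    drop = [c for c in ("image_id", "label", "error") if c in table.columns]
    cols = [c for c in table.columns if c not in drop]
    X = table[cols].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    return X, y, cols


def make_model(config: SvmConfig) -> Pipeline:
    """Imputation -> (scaling) -> RBF SVM, as one leak-proof pipeline."""
    steps = [("impute", SimpleImputer(strategy="median"))]
    if config.scaling == "standardize":
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(kernel="rbf")))
    return Pipeline(steps)


def _param_grid(config: SvmConfig) -> dict:
    n = config.grid_points_per_axis
    return {
        "svm__C": np.logspace(*np.log10(config.c_range), n),
        "svm__gamma": np.logspace(*np.log10(config.gamma_range), n),
    }


def cross_validate(table: pd.DataFrame, config: SvmConfig | None = None) -> MetricsReport:
    """Stratified outer CV with inner grid search; metrics on pooled predictions."""
    config = config or SvmConfig()
    X, y, cols = _feature_matrix(table)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if counts.min() < config.cv_folds:
        raise ValueError(
            "each class needs >= cv_folds samples (%d < %d)"
            % (counts.min(), config.cv_folds)
        )
    outer = StratifiedKFold(config.cv_folds, shuffle=True, random_state=config.seed)
    inner = StratifiedKFold(3, shuffle=True, random_state=config.seed + 1)
    base = make_model(config)
    grid = _param_grid(config)
    pred = np.empty_like(y)
    score = np.empty(len(y), dtype=float)
    chosen = []
    for train, test in outer.split(X, y):
        search = GridSearchCV(clone(base), grid, cv=inner, scoring="accuracy", n_jobs=1)
        search.fit(X[train], y[train])
        pred[test] = search.predict(X[test])
        score[test] = search.decision_function(X[test])
        chosen.append(
            {k.removeprefix("svm__"): float(v) for k, v in search.best_params_.items()}
        )
    conf = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fn=int(np.sum((pred == 0) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
    )
    report = compute_metrics(conf)
    report.auc, report.roc_points = roc_auc(score, y)
    report.details = {
        "folds": config.cv_folds,
        "chosen_params": chosen,
        "feature_columns": cols,
        "seed": config.seed,
        "scaling": config.scaling,
    }
    return report


# ---------------------------------------------------------------------------
# spectrum threshold rule
# ---------------------------------------------------------------------------

def decision_threshold(
    alpha_healthy, alpha_pathological, feature: tuple[str, str] = ("bimf_1", "alpha0")
) -> ThresholdRule:
    """Midpoint rule: (max pathological alpha + min healthy alpha) / 2."""
    healthy = np.asarray(alpha_healthy, dtype=float)
    path = np.asarray(alpha_pathological, dtype=float)
    if healthy.size == 0 or path.size == 0:
        raise ValueError("both populations must be nonempty")
    thr = 0.5 * (float(path.max()) + float(healthy.min()))
    return ThresholdRule(threshold=thr, feature=feature)


def classify_by_threshold(features: pd.DataFrame, rule: ThresholdRule) -> pd.Series:
    """Label 1 iff the rule's feature is strictly below the threshold.

    A value exactly at the threshold is negative ("lower than" is strict);
    a missing feature yields a pandas NA (abstention), reported separately
    from errors by the caller.
    """
    if rule.column not in features.columns:
        raise ValueError("feature column %r not in table" % (rule.column,))
    vals = features[rule.column].astype(float)
    out = pd.Series(pd.NA, index=features.index, dtype="Int64", name="prediction")
    ok = vals.notna()
    out[ok] = (vals[ok] < rule.threshold).astype(int)
    return out
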