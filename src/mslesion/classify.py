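"""Serial feature fusion, binary classifiers, cross-validation and metrics.

The positive class is MS, encoded 1 (normal is 0). Metrics are reported on
the percent scale, rounded half-up to two decimals:

    AC = (TP + TN) / (TP + TN + FP + FN)
    PR = TP / (TP + FP)
    SE = TP / (TP + FN)
    SP = TN / (TN + FP)
    FS = 2 TP / (2 TP + FN + FP)

A zero denominator yields 0.00 with a warning rather than a non-finite value.
The headline evaluation is stratified five-fold cross-validation with
feature standardization fit on the training folds only; per-fold confusion
counts are pooled and the metric suite is computed from the pooled counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import ConfigurationError, DataValidationError, DimensionError

CLASSIFIERS = ("SM", "DT", "RF", "NB", "KNN", "SVM-L", "SVM-RBF")

REPORT_COLUMNS = ["Scheme", "TP", "FN", "TN", "FP", "AC", "PR", "SE", "SP", "FS"]


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FN/TN/FP for one binary evaluation (positive class = MS = 1)."""

    TP: int
    FN: int
    TN: int
    FP: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FN, self.TN, self.FP) < 0:
            raise DataValidationError(f"counts must be non-negative: {self}")

    @property
    def total(self) -> int:
        return self.TP + self.FN + self.TN + self.FP

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP, self.FN + other.FN, self.TN + other.TN, self.FP + other.FP
        )


@dataclass(frozen=True)
class MetricsReport:
    """AC/PR/SE/SP/FS on the percent scale, rounded half-up to 2 decimals."""

    AC: float
    PR: float
    SE: float
    SP: float
    FS: float


def _round2(value: float) -> float:
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"zero denominator for {name}; reporting 0", stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Metric suite from confusion counts, on the rounded percent scale."""
    if counts.total == 0:
        raise DataValidationError("cannot compute metrics on zero evaluated samples")
    tp, fn, tn, fp = counts.TP, counts.FN, counts.TN, counts.FP
    ac = (tp + tn) / counts.total
    pr = _ratio(tp, tp + fp, "PR")
    se = _ratio(tp, tp + fn, "SE")
    sp = _ratio(tn, tn + fp, "SP")
    fs = _ratio(2 * tp, 2 * tp + fn + fp, "FS")
    return MetricsReport(
        AC=_round2(100 * ac),
        PR=_round2(100 * pr),
        SE=_round2(100 * se),
        SP=_round2(100 * sp),
        FS=_round2(100 * fs),
    )


@dataclass
class CVResult:
    """Pooled five-fold cross-validation outcome for one classifier."""

    classifier_name: str
    per_fold: list[ConfusionCounts]
    pooled: ConfusionCounts
    report: MetricsReport
    scores: np.ndarray = field(default=None, repr=False)  # held-out MS scores
    score_labels: np.ndarray = field(default=None, repr=False)


def serial_fuse(df_selected: np.ndarray, hcf_selected: np.ndarray) -> np.ndarray:
    """Row-wise concatenation [deep | hand-crafted]; width k1 + k2."""
    a = np.asarray(df_selected, dtype=np.float64)
    b = np.asarray(hcf_selected, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2:
        raise DimensionError("both blocks must be 2D matrices")
    if a.shape[1] < 1 or b.shape[1] < 1:
        raise DimensionError("both blocks must have at least one feature column")
    if a.shape[0] != b.shape[0]:
        raise DimensionError(f"row count mismatch: {a.shape[0]} vs {b.shape[0]}")
    return np.hstack([a, b])


def make_classifier(name: str, seed: int = 0) -> Pipeline:
    """A seeded sklearn Pipeline (train-fold standardization + classifier).

    Fixed hyperparameters: KNN k=5 Euclidean, RF 100 trees, SVM C=1 with
    gamma = 1/d for the RBF kernel, Gaussian NB, Gini decision tree of
    unlimited depth, and a softmax/logistic discriminant for SM.
    """
    if name not in CLASSIFIERS:
        raise ConfigurationError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")
    if name == "SM":
        clf = LogisticRegression(max_iter=5000, random_state=seed)
    elif name == "DT":
        clf = DecisionTreeClassifier(criterion="gini", random_state=seed)
    elif name == "RF":
        clf = RandomForestClassifier(n_estimators=100, random_state=seed)
    elif name == "NB":
        clf = GaussianNB()
    elif name == "KNN":
        clf = KNeighborsClassifier(n_neighbors=5, metric="euclidean")
    elif name == "SVM-L":
        clf = SVC(kernel="linear", C=1.0, random_state=seed)
    else:  # SVM-RBF
        clf = SVC(kernel="rbf", C=1.0, gamma="auto", random_state=seed)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _check_two_classes(y: np.ndarray) -> None:
    if np.unique(y).size != 2:
        raise DataValidationError("need samples from both classes")


def train_classifier(
    features: np.ndarray, labels: np.ndarray, name: str, seed: int = 0
) -> Pipeline:
    """Fit one of the seven classifiers on (features, 0/1 labels)."""
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    _check_two_classes(y)
    model = make_classifier(name, seed)
    model.fit(X, y)
    return model


def _ms_scores(model: Pipeline, X: np.ndarray) -> np.ndarray:
    """Continuous MS-class score for ROC analysis."""
    clf = model.named_steps["clf"]
    if hasattr(clf, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
    )


def five_fold_cv(
    features: np.ndarray,
    labels: np.ndarray,
    name: str,
    seed: int = 0,
    n_folds: int = 5,
) -> CVResult:
    """Stratified k-fold evaluation with pooled confusion counts.

    Standardization statistics are fit on each training fold only, so no
    information leaks from the held-out fold.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    _check_two_classes(y)
    counts = np.bincount(y)
    if counts.min() < n_folds:
        raise DataValidationError(
            f"need >= {n_folds} samples per class, got {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    per_fold = []
    scores = np.empty(len(y))
    for train_idx, test_idx in skf.split(X, y):
        model = train_classifier(X[train_idx], y[train_idx], name, seed)
        y_pred = model.predict(X[test_idx])
        per_fold.append(confusion_from_predictions(y[test_idx], y_pred))
        scores[test_idx] = _ms_scores(model, X[test_idx])
    pooled = per_fold[0]
    for c in per_fold[1:]:
        pooled = pooled + c
    return CVResult(
        classifier_name=name,
        per_fold=per_fold,
        pooled=pooled,
        report=compute_metrics(pooled),
        scores=scores,
        score_labels=y,
    )


def roc_curve_points(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """(FPR, TPR) at every threshold between distinct scores; trapezoid area.

    Returns an (m, 2) array of curve points ordered from (0, 0) to (1, 1).
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(int)
    if not np.isfinite(s).all():
        raise DataValidationError("scores must be finite")
    _check_two_classes(y)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last point of each tied-score run (thresholds between
    # distinct scores), plus the origin
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    area = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), area


def report_tables(results: list[CVResult], out: str | Path | None = None) -> pd.DataFrame:
    """One row per classifier: Scheme, TP, FN, TN, FP, AC, PR, SE, SP, FS."""
    if not results:
        raise DataValidationError("no results to report")
    rows = []
    for r in results:
        c, m = r.pooled, r.report
        rows.append(
            dict(
                Scheme=r.classifier_name,
                TP=c.TP, FN=c.FN, TN=c.TN, FP=c.FP,
                AC=m.AC, PR=m.PR, SE=m.SE, SP=m.SP, FS=m.FS,
            )
        )
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if out is not None:
        table.to_csv(Path(out), index=False, float_format="%.2f")
    return table
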