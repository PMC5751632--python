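"""Confusion-matrix metrics, ROC threshold sweep, cross-validation and
per-activity error analysis.

Metrics follow the usual binary-recognition definitions over windows:
accuracy (TP+TN)/total, precision TP/(TP+FP), sensitivity TP/(TP+FN),
specificity TN/(FP+TN), all reported as percentages.  Ratios with a zero
denominator are *not applicable* (``None``), never silently 0.  Reported
values round to two decimals; unrounded values are retained internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import classify
from .model import train_model
from .structure import ModularBNStructure
from .windows import WindowFeatureVector


@dataclass
class ConfusionMatrix:
    """Window counts: eating is the positive class."""

    tp: int = 0
    fn: int = 0
    fp: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def add(self, decision_eating: bool, truth_eating: bool) -> None:
        if truth_eating:
            if decision_eating:
                self.tp += 1
            else:
                self.fn += 1
        else:
            if decision_eating:
                self.fp += 1
            else:
                self.tn += 1

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp, self.fn + other.fn, self.fp + other.fp, self.tn + other.tn
        )


@dataclass
class MetricsReport:
    """Percent metrics; ``None`` marks a not-applicable (0/0) ratio."""

    accuracy: float | None
    precision: float | None
    sensitivity: float | None
    specificity: float | None

    def rounded(self) -> dict[str, float | None]:
        """Two-decimal reporting view, matching how results are printed."""
        return {
            k: (None if v is None else round(v, 2))
            for k, v in vars(self).items()
        }


@dataclass
class ROCPoint:
    threshold: float
    sensitivity: float
    one_minus_specificity: float


def _ratio_pct(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Percent accuracy/precision/sensitivity/specificity from a confusion matrix."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return MetricsReport(
        accuracy=_ratio_pct(cm.tp + cm.tn, cm.total),
        precision=_ratio_pct(cm.tp, cm.tp + cm.fp),
        sensitivity=_ratio_pct(cm.tp, cm.tp + cm.fn),
        specificity=_ratio_pct(cm.tn, cm.fp + cm.tn),
    )


def roc_sweep(
    posteriors: list[tuple[float, bool]],
    thresholds: list[float] | None = None,
) -> tuple[list[ROCPoint], float]:
    """Sweep the decision threshold and trace the ROC curve.

    ``posteriors`` pairs each window's eating posterior with its truth.
    ``thresholds`` must be descending (default: 1.0 down to 0.0 in steps of
    0.05); each threshold classifies with the same tie rule as recognition
    (posterior >= threshold -> eating).  Returns the ROC points and the
    trapezoidal AUC over the swept curve anchored at (0,0) and (1,1).
    """
    if not posteriors:
        raise ValueError("no posteriors to sweep")
    if thresholds is None:
        thresholds = [round(t, 2) for t in np.arange(1.0, -0.001, -0.05)]
    if any(t < 0 or t > 1 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    if list(thresholds) != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be descending")

    points = []
    for thr in thresholds:
        cm = ConfusionMatrix()
        for p, truth in posteriors:
            cm.add(classify(p, thr) == "eating", truth)
        sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else 0.0
        spec = cm.tn / (cm.fp + cm.tn) if (cm.fp + cm.tn) else 1.0
        points.append(ROCPoint(thr, sens, 1.0 - spec))

    xs = [0.0] + [p.one_minus_specificity for p in points] + [1.0]
    ys = [0.0] + [p.sensitivity for p in points] + [1.0]
    order = np.argsort(xs, kind="stable")
    auc = float(np.trapezoid(np.array(ys)[order], np.array(xs)[order]))
    return points, auc


def stratified_folds(
    labels: np.ndarray, k: int, seed: int
) -> np.ndarray:
    """Deterministic stratified fold assignment (fold index per sample).

    Samples of each class are shuffled with the seed and dealt round-robin,
    so fold sizes differ by at most one and the assignment depends only on
    the multiset of labels and the seed-driven permutation.
    """
    rng = np.random.default_rng(seed)
    fold = np.empty(len(labels), dtype=np.int64)
    counter = 0
    for cls in np.unique(labels):
        idx = np.nonzero(labels == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        for j, i in enumerate(idx):
            fold[i] = (counter + j) % k
        counter += len(idx)
    return fold


@dataclass
class CVReport:
    fold_matrices: list[ConfusionMatrix]
    fold_metrics: list[MetricsReport]
    pooled: ConfusionMatrix
    pooled_metrics: MetricsReport
    mean_accuracy: float
    sd_accuracy: float


def kfold_cv(
    windows: list[WindowFeatureVector],
    annotations: pd.DataFrame,
    structure: ModularBNStructure,
    k: int = 10,
    seed: int = 0,
    threshold: float = 0.6,
    alpha: float = 1.0,
) -> CVReport:
    """Stratified k-fold cross-validation at the window level.

    Windows are canonically ordered by start time before fold assignment, so
    shuffling the input does not change the folds.  Each fold trains stumps
    and CPTs on the other k-1 folds and classifies the held-out windows at
    the given threshold.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    windows = sorted(windows, key=lambda w: w.window_start)
    labels = np.array([w.is_eating for w in windows])
    if labels.all() or not labels.any():
        raise ValueError("dataset must contain both classes")
    folds = stratified_folds(labels, k, seed)

    fold_matrices: list[ConfusionMatrix] = []
    fold_metrics: list[MetricsReport] = []
    for f in range(k):
        train_idx = np.nonzero(folds != f)[0]
        test_idx = np.nonzero(folds == f)[0]
        test_labels = labels[test_idx]
        if test_labels.all() or not test_labels.any():
            warnings.warn(f"fold {f} contains a single class; some metrics not applicable")
        model = train_model(
            [windows[i] for i in train_idx], annotations, structure, alpha, threshold
        )
        cm = ConfusionMatrix()
        for i in test_idx:
            rep = model.posterior(windows[i].features)
            cm.add(rep.decision == "eating", windows[i].is_eating)
        fold_matrices.append(cm)
        fold_metrics.append(compute_metrics(cm))

    pooled = ConfusionMatrix()
    for cm in fold_matrices:
        pooled = pooled + cm
    accs = [m.accuracy for m in fold_metrics if m.accuracy is not None]
    return CVReport(
        fold_matrices=fold_matrices,
        fold_metrics=fold_metrics,
        pooled=pooled,
        pooled_metrics=compute_metrics(pooled),
        mean_accuracy=float(np.mean(accs)),
        sd_accuracy=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
    )


def per_activity_error(
    decisions: list[tuple[int, str, bool]]
) -> pd.DataFrame:
    """Per-activity error rate and share of the total error.

    ``decisions`` rows are ``(activity label, decision, truth_is_eating)``.
    Error rate = errors(activity) / windows(activity); error share =
    errors(activity) / total errors (``None`` when there are no errors).
    Shares sum to 1 whenever any error occurred.
    """
    if not decisions:
        raise ValueError("no decisions")
    df = pd.DataFrame(decisions, columns=["activity", "decision", "truth"])
    df["error"] = (df["decision"] == "eating") != df["truth"]
    total_errors = int(df["error"].sum())
    rows = []
    for act, grp in df.groupby("activity"):
        errs = int(grp["error"].sum())
        rows.append(
            {
                "activity": int(act),
                "windows": len(grp),
                "errors": errs,
                "error_rate": errs / len(grp),
                "error_share": errs / total_errors if total_errors else None,
            }
        )
    return pd.DataFrame(rows).set_index("activity")
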