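"""Metrics arithmetic, ROC sweep, cross-validation and error analysis."""

import numpy as np
import pytest

from eatbn.evaluate import (
    ConfusionMatrix,
    compute_metrics,
    kfold_cv,
    per_activity_error,
    roc_sweep,
    stratified_folds,
)
from eatbn.simulate import context_truth, load_default_profiles
from eatbn.structure import build_default_structure
from eatbn.windows import FEATURE_NAMES, WindowFeatureVector


class TestComputeMetrics:
    def test_published_confusion_matrix(self):
        # the pooled 379,013-window matrix of the original study
        m = compute_metrics(ConfusionMatrix(tp=136354, fn=42937, fp=33949, tn=165773))
        r = m.rounded()
        assert r["accuracy"] == 79.71
        assert r["precision"] == 80.07
        assert r["sensitivity"] == 76.05
        assert r["specificity"] == 83.00

    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(tp=10, fn=0, fp=0, tn=10))
        assert all(v == 100.0 for v in vars(m).values())

    def test_zero_denominator_is_not_applicable(self):
        m = compute_metrics(ConfusionMatrix(tp=0, fn=0, fp=5, tn=5))
        assert m.precision == 0.0  # 0 TP out of 5 positives
        assert m.sensitivity is None  # no actual eating windows
        assert m.specificity == 50.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionMatrix())

    def test_accuracy_between_class_rates(self):
        cm = ConfusionMatrix(tp=30, fn=10, fp=5, tn=55)
        m = compute_metrics(cm)
        assert min(m.sensitivity, m.specificity) <= m.accuracy <= max(
            m.sensitivity, m.specificity
        )


def oracle_roc_point(pairs, thr):
    tp = sum(1 for p, t in pairs if p >= thr and t)
    fn = sum(1 for p, t in pairs if p < thr and t)
    fp = sum(1 for p, t in pairs if p >= thr and not t)
    tn = sum(1 for p, t in pairs if p < thr and not t)
    return tp / (tp + fn), 1 - tn / (fp + tn)


class TestROCSweep:
    pairs = [(0.9, True), (0.7, True), (0.65, False), (0.5, True), (0.3, False), (0.1, False)]

    def test_zero_threshold_catches_everything(self):
        points, _ = roc_sweep(self.pairs, thresholds=[1.0, 0.5, 0.0])
        assert points[-1].sensitivity == 1.0
        assert points[-1].one_minus_specificity == 1.0

    def test_perfect_separation_auc_one(self):
        pairs = [(0.9, True), (0.8, True), (0.2, False), (0.1, False)]
        _, auc = roc_sweep(pairs)
        assert auc == pytest.approx(1.0)

    def test_hand_enumerated_points(self):
        thresholds = [1.0, 0.8, 0.6, 0.4, 0.2, 0.0]
        points, auc = roc_sweep(self.pairs, thresholds)
        for point in points:
            sens, fpr = oracle_roc_point(self.pairs, point.threshold)
            assert point.sensitivity == pytest.approx(sens)
            assert point.one_minus_specificity == pytest.approx(fpr)
        assert 0.0 <= auc <= 1.0

    def test_sensitivity_monotone_in_descending_thresholds(self):
        rng = np.random.default_rng(2)
        pairs = [(float(p), bool(t)) for p, t in zip(rng.random(200), rng.random(200) < 0.4)]
        points, _ = roc_sweep(pairs)
        sens = [p.sensitivity for p in points]
        assert sens == sorted(sens)

    def test_requires_descending_thresholds(self):
        with pytest.raises(ValueError, match="descending"):
            roc_sweep(self.pairs, thresholds=[0.2, 0.8])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            roc_sweep([])


def separable_dataset(n_per_class=40):
    """Hand-built perfectly learnable windows + consistent annotations."""
    import pandas as pd

    profiles = load_default_profiles()
    truth_eat = context_truth(4, profiles[4].true_contexts)
    truth_not = context_truth(2, frozenset())
    windows, ann_rows = [], []
    for i in range(2 * n_per_class):
        eating = i % 2 == 0
        value = 10.0 if eating else 0.0
        ws = float(i)
        windows.append(
            WindowFeatureVector(
                window_start=ws,
                features={f: value for f in FEATURE_NAMES},
                label=4 if eating else 2,
                is_eating=eating,
            )
        )
        truth = truth_eat if eating else truth_not
        ann_rows.extend((ws, nid, state) for nid, state in truth.items())
    annotations = pd.DataFrame(ann_rows, columns=["window_start", "node_id", "state"])
    return windows, annotations


class TestKFoldCV:
    def test_perfectly_learnable_dataset_scores_100(self):
        windows, annotations = separable_dataset()
        report = kfold_cv(windows, annotations, build_default_structure(), k=2, seed=0)
        assert report.pooled_metrics.accuracy == 100.0

    def test_fold_assignment_deterministic(self):
        labels = np.random.default_rng(1).random(101) < 0.4
        a = stratified_folds(labels, 10, seed=3)
        b = stratified_folds(labels, 10, seed=3)
        assert (a == b).all()
        assert not (a == stratified_folds(labels, 10, seed=4)).all()

    def test_fold_sizes_differ_by_at_most_one(self):
        labels = np.random.default_rng(1).random(103) < 0.3
        folds = stratified_folds(labels, 10, seed=0)
        sizes = np.bincount(folds, minlength=10)
        assert sizes.max() - sizes.min() <= 2  # +-1 per class stratum

    def test_shuffled_input_same_pooled_matrix(self):
        windows, annotations = separable_dataset(n_per_class=20)
        rng = np.random.default_rng(8)
        shuffled = [windows[i] for i in rng.permutation(len(windows))]
        structure = build_default_structure()
        a = kfold_cv(windows, annotations, structure, k=3, seed=1)
        b = kfold_cv(shuffled, annotations, structure, k=3, seed=1)
        assert vars(a.pooled) == vars(b.pooled)

    def test_single_class_dataset_rejected(self):
        windows, annotations = separable_dataset(n_per_class=10)
        eating_only = [w for w in windows if w.is_eating]
        with pytest.raises(ValueError, match="both classes"):
            kfold_cv(eating_only, annotations, build_default_structure(), k=2, seed=0)


class TestPerActivityError:
    def test_zero_errors(self):
        rows = [(4, "eating", True), (2, "non-eating", False)]
        out = per_activity_error(rows)
        assert (out["error_rate"] == 0).all()
        assert out["error_share"].isna().all()

    def test_hand_counts(self):
        rows = (
            [(4, "eating", True)] * 6 + [(4, "non-eating", True)] * 4  # 4/10 errors
            + [(8, "eating", False)] * 3 + [(8, "non-eating", False)] * 7  # 3/10
            + [(2, "non-eating", False)] * 5  # 0/5
        )
        out = per_activity_error(rows)
        assert out.loc[4, "error_rate"] == pytest.approx(0.4)
        assert out.loc[8, "error_rate"] == pytest.approx(0.3)
        assert out.loc[2, "error_rate"] == 0.0
        assert out.loc[4, "error_share"] == pytest.approx(4 / 7)
        assert out.loc[8, "error_share"] == pytest.approx(3 / 7)

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(0)
        rows = [
            (int(rng.integers(1, 11)),
             "eating" if rng.random() < 0.5 else "non-eating",
             bool(rng.random() < 0.5))
            for _ in range(200)
        ]
        out = per_activity_error(rows)
        if out["errors"].sum() > 0:
            assert out["error_share"].sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            per_activity_error([])
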