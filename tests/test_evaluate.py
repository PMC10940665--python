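"""Confusion metrics, ROC/PR areas, cross-validation and the tree sweep."""

import math

import numpy as np
import pytest

from multippi.evaluate import (ConfusionCounts, RFConfig, compute_metrics,
                               kfold_cv, pr_aupr, roc_auc, sweep_trees,
                               train_predict)
from multippi.pairs import PairFeatureMatrix, PPIPair


def rank_statistic(scores, labels):
    """Brute-force AUC: fraction of positive-negative pairs correctly ordered."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def step_aupr(scores, labels):
    """Hand enumeration of the step-wise PR area at each distinct threshold."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    sorted_scores = np.asarray(scores)[order]
    sorted_labels = np.asarray(labels)[order]
    n_pos = sorted_labels.sum()
    area, prev_recall = 0.0, 0.0
    tp = fp = 0
    i = 0
    while i < len(sorted_scores):
        j = i
        while j < len(sorted_scores) and sorted_scores[j] == sorted_scores[i]:
            tp += sorted_labels[j]
            fp += 1 - sorted_labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


class TestConfusionMetrics:
    def test_worked_example(self):
        r = compute_metrics(ConfusionCounts(tp=50, tn=40, fp=10, fn=0))
        assert r.acc == pytest.approx(0.90)
        assert r.sen == pytest.approx(1.0)
        assert r.spec == pytest.approx(0.80)
        assert r.prec == pytest.approx(50 / 60)

    def test_perfect_classifier_mcc_one(self):
        r = compute_metrics(ConfusionCounts(tp=7, tn=7, fp=0, fn=0))
        assert r.mcc == pytest.approx(1.0)

    def test_accuracy_symmetric_under_class_swap(self):
        a = compute_metrics(ConfusionCounts(tp=30, tn=20, fp=5, fn=9))
        b = compute_metrics(ConfusionCounts(tp=20, tn=30, fp=9, fn=5))
        assert a.acc == pytest.approx(b.acc)

    def test_mcc_zero_denominator_convention(self):
        with pytest.warns(UserWarning):
            r = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
        assert r.mcc == 0.0

    def test_no_predicted_positive_warns(self):
        with pytest.warns(UserWarning, match="precision"):
            r = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=3))
        assert r.prec == 0.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(tp=0, tn=0, fp=0, fn=0))

    def test_matches_direct_formula_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            tp, tn, fp, fn = (int(x) for x in rng.integers(1, 200, size=4))
            r = compute_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
            assert abs(r.spec - tn / (fp + tn)) < 1e-12
            assert abs(r.prec - tp / (fp + tp)) < 1e-12
            assert abs(r.sen - tp / (tp + fn)) < 1e-12
            assert abs(r.acc - (tp + tn) / (tp + fp + tn + fn)) < 1e-12
            mcc = ((tp * tn - fp * fn)
                   / math.sqrt((tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)))
            assert abs(r.mcc - mcc) < 1e-12


class TestROC:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == pytest.approx(1.0)

    def test_worked_example(self):
        auc, _ = roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert auc == pytest.approx(0.75)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(21)
        scores = rng.random(4000)
        labels = rng.integers(0, 2, size=4000)
        auc, _ = roc_auc(scores, labels)
        assert abs(auc - 0.5) < 0.05

    def test_matches_rank_statistic(self):
        rng = np.random.default_rng(33)
        for _ in range(30):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.random(n), 2)  # force some ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(rank_statistic(scores, labels),
                                        abs=1e-12)

    @pytest.mark.parametrize("transform", [np.exp, lambda s: 3 * s + 1,
                                           lambda s: s ** 3])
    def test_invariant_under_monotone_transform(self, transform):
        rng = np.random.default_rng(4)
        scores = rng.random(100)
        labels = rng.integers(0, 2, size=100)
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(transform(scores), labels)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])


class TestPR:
    def test_perfect_ranking(self):
        aupr, _ = pr_aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert aupr == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        aupr, _ = pr_aupr([0.5] * 10, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        assert aupr == pytest.approx(0.3)

    def test_worked_example_matches_enumeration(self):
        scores, labels = [0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]
        aupr, _ = pr_aupr(scores, labels)
        assert aupr == pytest.approx(step_aupr(scores, labels), abs=1e-12)
        assert aupr == pytest.approx(0.5 + 0.5 * 2 / 3, abs=1e-12)

    def test_matches_enumeration_on_random_sets(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.random(n), 2)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() == 0:
                labels[0] = 1
            aupr, _ = pr_aupr(scores, labels)
            assert aupr == pytest.approx(step_aupr(scores, labels), abs=1e-10)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_aupr([0.1, 0.2], [0, 0])


def toy_matrix(n=200, width=10, seed=0, signal=2.0):
    """Linearly separable-ish two-class pair matrix."""
    rng = np.random.default_rng(seed)
    y = np.repeat([1, 0], n // 2)
    X = rng.normal(size=(n, width)) + signal * y[:, None] * np.linspace(
        0, 1, width)
    pairs = [PPIPair(f"a{i:04d}", f"b{i:04d}", int(label))
             for i, label in enumerate(y)]
    return PairFeatureMatrix(pairs=pairs, X=X, y=y)


class TestRFAndCV:
    def test_scores_in_range_and_deterministic(self):
        m = toy_matrix()
        rf = RFConfig(n_trees=40, seed=3)
        s1 = train_predict(m.X[:150], m.y[:150], m.X[150:], rf)
        s2 = train_predict(m.X[:150], m.y[:150], m.X[150:], rf)
        assert np.array_equal(s1, s2)
        assert s1.min() >= 0 and s1.max() <= 1

    def test_memorized_positive_scores_high(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        X[:20] = X[0]                    # one heavily repeated positive
        y = np.repeat([1, 0], 20)
        s = train_predict(X, y, X[0:1], RFConfig(n_trees=50, seed=0))
        assert s[0] > 0.5

    def test_dimension_mismatch_rejected(self):
        m = toy_matrix()
        with pytest.raises(ValueError, match="mismatch"):
            train_predict(m.X, m.y, m.X[:, :5], RFConfig(n_trees=5))

    def test_single_class_training_rejected(self):
        m = toy_matrix()
        with pytest.raises(ValueError):
            train_predict(m.X[m.y == 1], m.y[m.y == 1], m.X,
                          RFConfig(n_trees=5))

    def test_folds_partition_evenly_and_stratified(self):
        m = toy_matrix(n=1000, seed=2)
        cv = kfold_cv(m, RFConfig(n_trees=10, seed=0), k=5, seed=0)
        sizes = [np.sum(cv.fold_assignment == f) for f in range(5)]
        assert sizes == [200] * 5
        for f in range(5):
            in_fold = cv.fold_assignment == f
            assert abs(m.y[in_fold].sum() - 100) <= 1
        assert sorted(np.unique(cv.fold_assignment)) == [0, 1, 2, 3, 4]

    def test_mean_and_sd_reported_per_metric(self):
        m = toy_matrix(n=200)
        cv = kfold_cv(m, RFConfig(n_trees=20, seed=0), k=5, seed=1)
        for name in ("spec", "mcc", "prec", "sen", "acc", "auc", "aupr"):
            assert name in cv.mean and name in cv.sd
        assert 0.5 < cv.mean["auc"] <= 1.0

    def test_k_larger_than_minority_rejected(self):
        m = toy_matrix(n=8)
        with pytest.raises(ValueError):
            kfold_cv(m, RFConfig(n_trees=5), k=6, seed=0)


class TestSweep:
    def test_shape_and_shared_folds(self):
        m = toy_matrix(n=120, seed=5)
        table, assignment = sweep_trees(m, RFConfig(seed=0),
                                        grid=[10, 20, 30], k=5, seed=3)
        assert list(table.columns) == [10, 20, 30]
        assert list(table.index) == ["fold0", "fold1", "fold2", "fold3",
                                     "fold4", "mean", "sd"]
        # Shared folds: the assignment is computed once for the whole grid
        # and equals the assignment kfold_cv derives from the same seed.
        cv = kfold_cv(m, RFConfig(n_trees=10, seed=0), k=5, seed=3)
        assert np.array_equal(assignment, cv.fold_assignment)
        assert table.loc["fold0", 10] == pytest.approx(cv.folds[0].acc)

    def test_default_grid_has_nine_points(self):
        import inspect
        default = inspect.signature(sweep_trees).parameters["grid"].default
        assert list(default) == [180, 200, 220, 240, 260, 280, 300, 320, 340]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_trees(toy_matrix(), RFConfig(), grid=[], k=2, seed=0)
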