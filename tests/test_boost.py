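"""Boosting stage: splits, weights, tuning, metrics."""

import numpy as np
import pytest

from boostsel.boost import (
    HyperParams,
    SearchSpace,
    class_weights,
    largest_remainder_allocation,
    metric_report,
    metrics_from_predictions,
    stratified_split,
    train_eval,
    tune,
)
from boostsel.genotype import PhenotypeTable
from boostsel.simulate import SimulationConfig, simulate_dataset

FAST_SPACE = SearchSpace(max_rounds=40, early_stopping_rounds=35)


def _phenos(counts: dict) -> PhenotypeTable:
    assignments = {}
    i = 0
    for lab, n in counts.items():
        for _ in range(n):
            assignments[f"S{i}"] = lab
            i += 1
    return PhenotypeTable(assignments=assignments, class_set=list(counts))


class TestStratifiedSplit:
    def test_cohort_allocation(self):
        """45/27/23 with 24 held out gives test (11, 7, 6), train (34, 20, 17)."""
        ph = _phenos({"white": 45, "beige": 27, "orange": 23})
        split = stratified_split(ph, 24, seed=47)
        test_counts = {c: 0 for c in ph.class_set}
        for s in split.test_ids:
            test_counts[ph.assignments[s]] += 1
        assert test_counts == {"white": 11, "beige": 7, "orange": 6}
        train_counts = {c: 0 for c in ph.class_set}
        for s in split.train_ids:
            train_counts[ph.assignments[s]] += 1
        assert train_counts == {"white": 34, "beige": 20, "orange": 17}

    def test_exact_proportional(self):
        ph = _phenos({"a": 10, "b": 10})
        split = stratified_split(ph, 4, seed=0)
        per_class = {c: 0 for c in "ab"}
        for s in split.test_ids:
            per_class[ph.assignments[s]] += 1
        assert per_class == {"a": 2, "b": 2}

    def test_zero_test_identity(self):
        ph = _phenos({"a": 3, "b": 2})
        split = stratified_split(ph, 0, seed=0)
        assert split.test_ids == []
        assert sorted(split.train_ids) == sorted(ph.assignments)

    def test_partition_property(self):
        ph = _phenos({"a": 13, "b": 7, "c": 5})
        split = stratified_split(ph, 6, seed=9)
        assert not set(split.train_ids) & set(split.test_ids)
        assert set(split.train_ids) | set(split.test_ids) == set(ph.assignments)

    def test_seed_changes_membership_not_counts(self):
        ph = _phenos({"a": 20, "b": 10})
        s1 = stratified_split(ph, 6, seed=1)
        s2 = stratified_split(ph, 6, seed=2)
        assert len(s1.test_ids) == len(s2.test_ids) == 6
        assert set(s1.test_ids) != set(s2.test_ids)

    def test_largest_remainder_tie_break_by_order(self):
        assert largest_remainder_allocation([10, 10], 3) == [2, 1]


class TestClassWeights:
    def test_equal_sizes_unit_weights(self):
        w = class_weights(["a"] * 5 + ["b"] * 5)
        assert w == {"a": 1.0, "b": 1.0}

    def test_unbalanced_weights(self):
        w = class_weights(["a", "b", "b", "b"])
        assert w["a"] == pytest.approx(2.0)
        assert w["b"] == pytest.approx(2 / 3)

    def test_weighted_mass_equal_across_classes(self):
        labels = ["a"] * 3 + ["b"] * 7 + ["c"] * 2
        w = class_weights(labels)
        masses = {c: w[c] * labels.count(c) for c in "abc"}
        assert len(set(round(v, 9) for v in masses.values())) == 1


@pytest.fixture(scope="module")
def trained(small_dataset):
    matrix, phenos, truth = small_dataset
    split = stratified_split(phenos, 30, seed=4)
    params, cv_auc = tune(
        matrix, phenos, split.train_ids, n_trials=3, n_folds=2, seed=21,
        space=FAST_SPACE,
    )
    fit = train_eval(matrix, phenos, split, params, cv_auc=cv_auc)
    return matrix, phenos, split, params, cv_auc, fit


class TestTune:
    def test_single_trial_returns_that_config(self, small_dataset):
        matrix, phenos, _ = small_dataset
        split = stratified_split(phenos, 30, seed=4)
        params, _ = tune(matrix, phenos, split.train_ids, n_trials=1,
                         n_folds=2, seed=5, space=FAST_SPACE)
        rng = np.random.default_rng(5)
        expected = FAST_SPACE.sample(rng)
        for f in ("max_depth", "min_child_weight", "gamma",
                  "colsample_bytree", "subsample", "learning_rate"):
            assert getattr(params, f) == getattr(expected, f)

    def test_same_seed_same_config(self, small_dataset):
        matrix, phenos, _ = small_dataset
        split = stratified_split(phenos, 30, seed=4)
        p1, a1 = tune(matrix, phenos, split.train_ids, n_trials=2, n_folds=2,
                      seed=8, space=FAST_SPACE)
        p2, a2 = tune(matrix, phenos, split.train_ids, n_trials=2, n_folds=2,
                      seed=8, space=FAST_SPACE)
        assert p1 == p2
        assert a1 == a2

    def test_strong_signal_high_cv_auc(self):
        """On the default simulated cohort (8 strong causal SNPs) the tuned
        cross-validated AUC clears 0.9."""
        matrix, phenos, _ = simulate_dataset(SimulationConfig(seed=1))
        split = stratified_split(phenos, 60, seed=4)
        _, cv_auc = tune(
            matrix, phenos, split.train_ids, n_trials=8, n_folds=4, seed=21,
            space=SearchSpace(max_rounds=120, early_stopping_rounds=35),
        )
        assert cv_auc >= 0.9

    def test_rejects_zero_trials(self, small_dataset):
        matrix, phenos, _ = small_dataset
        with pytest.raises(ValueError):
            tune(matrix, phenos, matrix.sample_ids, n_trials=0)


class TestTrainEval:
    def test_metrics_in_range_and_importance_positive(self, trained):
        fit = trained[5]
        m = fit.test_metrics
        assert 0 <= m["accuracy"] <= 1
        assert all(v > 0 for v in fit.importance.values())
        assert set(fit.importance) <= set(trained[0].site_ids)

    def test_accuracy_equals_confusion_trace(self, trained):
        m = trained[5].test_metrics
        cm = np.array(m["confusion"])
        assert m["accuracy"] == pytest.approx(np.trace(cm) / cm.sum())

    def test_signal_beats_majority_baseline(self, trained):
        matrix, phenos = trained[0], trained[1]
        counts = phenos.class_counts()
        majority = max(counts.values()) / sum(counts.values())
        assert trained[5].test_metrics["accuracy"] > majority

    def test_perfect_predictions(self):
        m = metrics_from_predictions(
            ["a", "a", "b", "b"], ["a", "a", "b", "b"], ["a", "b"]
        )
        assert m["accuracy"] == 1.0
        assert all(c["f1"] == 1.0 for c in m["per_class"].values())

    def test_majority_degenerate_predictor(self):
        # test counts (11, 7, 6), everything predicted as the largest class
        y_true = ["w"] * 11 + ["b"] * 7 + ["o"] * 6
        y_pred = ["w"] * 24
        m = metrics_from_predictions(y_true, y_pred, ["w", "b", "o"])
        assert m["accuracy"] == pytest.approx(11 / 24)

    def test_published_style_confusion_row(self):
        """Precision 1, recall 4/7, f1 0.73 for a class where 4 of 7 are
        recovered and nothing else is predicted into it."""
        y_true = ["b"] * 7 + ["o"] * 6 + ["w"] * 11
        y_pred = (["b"] * 4 + ["o"] * 3) + ["o"] * 6 + ["w"] * 11
        m = metrics_from_predictions(y_true, y_pred, ["b", "o", "w"])
        beige = m["per_class"]["b"]
        assert beige["precision"] == 1.0
        assert beige["recall"] == pytest.approx(4 / 7)
        assert beige["f1"] == pytest.approx(2 * (4 / 7) / (1 + 4 / 7))
        assert round(beige["f1"], 2) == 0.73


class TestMetricReport:
    def test_report_shape_and_support(self):
        y_true = ["a"] * 3 + ["b"] * 5
        y_pred = ["a", "a", "b", "b", "b", "b", "b", "a"]
        m = metrics_from_predictions(y_true, y_pred, ["a", "b"])
        table = metric_report(m)
        assert list(table.index) == ["a", "b", "accuracy", "macro avg", "weighted avg"]
        assert table.loc["a", "support"] + table.loc["b", "support"] == 8

    def test_weighted_f1_is_support_weighted(self):
        y_true = ["a"] * 2 + ["b"] * 6
        y_pred = ["a", "b", "b", "b", "b", "b", "a", "a"]
        m = metrics_from_predictions(y_true, y_pred, ["a", "b"])
        f1a = m["per_class"]["a"]["f1"]
        f1b = m["per_class"]["b"]["f1"]
        assert m["weighted"]["f1"] == pytest.approx((2 * f1a + 6 * f1b) / 8)


class TestHyperParams:
    def test_range_validation(self):
        with pytest.raises(ValueError):
            HyperParams(max_depth=0)
        with pytest.raises(ValueError):
            HyperParams(subsample=0.0)
        with pytest.raises(ValueError):
            HyperParams(learning_rate=1.5)

    def test_search_space_samples_within_bounds(self):
        rng = np.random.default_rng(0)
        space = SearchSpace()
        for _ in range(50):
            p = space.sample(rng)
            assert 2 <= p.max_depth <= 10
            assert 0 <= p.min_child_weight <= 10
            assert 0 <= p.gamma <= 5
            assert 0.3 <= p.colsample_bytree <= 1
            assert 0.5 <= p.subsample <= 1
            assert 0.01 <= p.learning_rate <= 0.3
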