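from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcdpipe import (ConfusionMatrix, ECMConfig, LabeledTable, PipelineConfig,
                     confusion, cross_validate, metrics, predict_ecm, train_ecm)
from bcdpipe.config import BHHOConfig
from bcdpipe.ecm_eval import f1_measure, mean_metrics, truncate_percent


def cluster_table(n_per_class=20, spread=0.3, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal([2.0, 2.0], spread, (n_per_class, 2))
    b = rng.normal([8.0, 8.0], spread, (n_per_class, 2))
    labels = np.array(["benign"] * n_per_class + ["malignant"] * n_per_class,
                      dtype=object)
    return LabeledTable(np.vstack([a, b]), labels, ["f1", "f2"])


class TestEnsemble:
    def test_separable_training_set_fit_perfectly_by_all_three(self, separable_table):
        model = train_ecm(separable_table)
        for clf in model.classifiers.values():
            assert np.all(clf.predict(separable_table.values)
                          == separable_table.labels.astype(str))

    def test_prediction_is_deterministic(self, separable_table):
        model = train_ecm(separable_table)
        a = predict_ecm(model, separable_table)
        b = predict_ecm(model, separable_table)
        assert np.array_equal(a, b)

    def test_single_class_table_rejected(self):
        table = LabeledTable(np.arange(12, dtype=float).reshape(6, 2),
                             np.array(["b"] * 6, dtype=object), ["f1", "f2"])
        with pytest.raises(ValueError):
            train_ecm(table)

    def test_too_few_instances_for_knn_rejected(self):
        table = LabeledTable(np.arange(10, dtype=float).reshape(5, 2),
                             np.array(["b", "b", "b", "m", "m"], dtype=object),
                             ["f1", "f2"], )
        with pytest.raises(ValueError):
            train_ecm(table, ECMConfig(knn_k=5))

    def test_feature_mismatch_rejected(self, separable_table):
        model = train_ecm(separable_table)
        bad = LabeledTable(np.ones((2, 3)), np.array(["b", "m"], dtype=object),
                           ["a", "b", "c"])
        with pytest.raises(ValueError):
            predict_ecm(model, bad)

    def test_majority_vote_matches_mode_oracle(self):
        table = cluster_table(n_per_class=50, spread=2.5, seed=1)
        model = train_ecm(table)
        test = cluster_table(n_per_class=50, spread=2.5, seed=2)
        ensemble = predict_ecm(model, test)
        base = {name: clf.predict(test.values)
                for name, clf in model.classifiers.items()}
        for i in range(test.n):
            votes = Counter(base[name][i] for name in base)
            assert votes[ensemble[i]] == max(votes.values())

    def test_unanimous_votes_always_win(self):
        table = cluster_table(seed=3)
        model = train_ecm(table)
        preds = predict_ecm(model, table)
        base = np.stack([clf.predict(table.values)
                         for clf in model.classifiers.values()])
        unanimous = np.all(base == base[0], axis=0)
        assert np.array_equal(preds[unanimous], base[0][unanimous])


class TestConfusion:
    def test_perfect_prediction_counts(self):
        y = np.array(["malignant"] * 3 + ["benign"] * 2)
        cm = confusion(y, y)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (3, 2, 0, 0)

    def test_inverted_prediction_counts(self):
        y = np.array(["malignant", "benign"])
        inv = np.array(["benign", "malignant"])
        cm = confusion(y, inv)
        assert (cm.tp, cm.tn) == (0, 0)
        assert (cm.fp, cm.fn) == (1, 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.array(["b"]), np.array(["b", "m"]))

    def test_matches_hand_tally_on_random_vectors(self):
        rng = np.random.default_rng(8)
        y_true = rng.choice(["benign", "malignant"], 20)
        y_pred = rng.choice(["benign", "malignant"], 20)
        cm = confusion(y_true, y_pred)
        tally = Counter(zip(y_true, y_pred))
        assert cm.tp == tally[("malignant", "malignant")]
        assert cm.tn == tally[("benign", "benign")]
        assert cm.fp == tally[("benign", "malignant")]
        assert cm.fn == tally[("malignant", "benign")]
        assert cm.total == 20


class TestMetrics:
    def test_basic_identities(self):
        m = metrics(ConfusionMatrix(tp=1, tn=1, fp=0, fn=0))
        assert m.accuracy == 1.0 and m.error == 0.0

    def test_accuracy_plus_error_is_one(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            counts = rng.integers(0, 30, 4)
            if counts.sum() == 0:
                continue
            m = metrics(ConfusionMatrix(*map(int, counts)))
            assert m.accuracy + m.error == pytest.approx(1.0)

    def test_self_prediction_scores_perfect(self):
        y = np.array(["malignant", "benign", "benign"])
        assert metrics(confusion(y, y)).accuracy == 1.0

    def test_zero_denominators_define_zero(self):
        m = metrics(ConfusionMatrix(tp=0, tn=5, fp=0, fn=0))
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)

    @pytest.mark.parametrize("p,r,expected", [
        (0.984, 0.980, 98.199),
        (0.944, 0.942, 94.299),
    ])
    def test_f1_truncated_percent_worked_examples(self, p, r, expected):
        assert truncate_percent(f1_measure(p, r)) == expected

    @settings(deadline=None, max_examples=60)
    @given(st.floats(0.01, 1.0), st.floats(0.01, 1.0))
    def test_f1_between_min_and_max_of_precision_recall(self, p, r):
        f1 = f1_measure(p, r)
        assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12

    def test_truncation_never_rounds_up(self):
        assert truncate_percent(0.9429999) == 94.299
        assert truncate_percent(0.013) == 1.3


def fast_config(seed=0, folds=5):
    cfg = PipelineConfig(seed=seed, cv_folds=folds)
    cfg.bhho = BHHOConfig(pop_size=5, it_max=5)
    return cfg


class TestCrossValidate:
    def test_five_equal_folds_on_ten_instances(self):
        table = cluster_table(n_per_class=5, seed=4)
        report = cross_validate(table, fast_config())
        sizes = np.bincount(report.fold_assignment)
        assert list(sizes) == [2, 2, 2, 2, 2]
        assert len(report.folds) == 5

    def test_fold_test_sets_partition_the_data(self):
        table = cluster_table(n_per_class=10, seed=5)
        report = cross_validate(table, fast_config())
        assert len(report.fold_assignment) == table.n
        assert set(report.fold_assignment) == set(range(5))

    def test_mean_equals_arithmetic_mean_of_folds(self):
        table = cluster_table(n_per_class=10, seed=6)
        report = cross_validate(table, fast_config(seed=1))
        for name in ("precision", "recall", "accuracy", "error", "f1"):
            assert getattr(report.mean, name) == pytest.approx(
                np.mean([getattr(f, name) for f in report.folds]))

    def test_perfectly_separable_data_scores_perfectly(self):
        table = cluster_table(n_per_class=10, seed=7)
        report = cross_validate(table, fast_config(seed=2))
        assert report.mean.accuracy == 1.0

    def test_class_too_small_to_stratify(self):
        table = cluster_table(n_per_class=3, seed=8)
        with pytest.raises(ValueError):
            cross_validate(table, fast_config(folds=5))

    def test_recomputed_mean_from_summed_confusions(self):
        reports = [metrics(ConfusionMatrix(2, 2, 0, 0)),
                   metrics(ConfusionMatrix(1, 2, 1, 0))]
        mean = mean_metrics(reports)
        assert mean.confusion.total == 8
        assert mean.accuracy == pytest.approx((1.0 + 0.75) / 2)
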