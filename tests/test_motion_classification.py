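"""Classifier construction, CV machinery and the evaluation metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roachloop.motion_classification import (
    ClassifierReport,
    ClassifierSpec,
    build_estimator,
    confusion_matrix_normalized,
    cross_validate,
    default_specs,
    evaluate_metrics,
    knn_default_k,
    select_best,
    train_classifier,
)

from conftest import synthetic_feature_table


class TestKnnRule:
    @pytest.mark.parametrize("n,k", [(900, 31), (100, 11), (1, 1), (17, 5)])
    def test_sqrt_rule_made_odd(self, n, k):
        assert knn_default_k(n) == k

    def test_rejects_empty_training_set(self):
        with pytest.raises(ValueError):
            knn_default_k(0)


class TestMetrics:
    def test_balanced_example(self):
        assert evaluate_metrics(9, 9, 1, 1) == pytest.approx((0.9, 0.9, 0.9, 0.9))

    def test_degenerate_zero_denominators(self):
        acc, prec, rec, f1 = evaluate_metrics(0, 5, 0, 5)
        assert (acc, prec, rec, f1) == (0.5, 0.0, 0.0, 0.0)

    def test_perfect_prediction(self):
        assert evaluate_metrics(10, 10, 0, 0) == (1.0, 1.0, 1.0, 1.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            evaluate_metrics(-1, 0, 0, 1)

    def test_label_swap_preserves_accuracy(self):
        tp, tn, fp, fn = 7, 11, 2, 3
        acc, *_ = evaluate_metrics(tp, tn, fp, fn)
        acc_swapped, *_ = evaluate_metrics(tn, tp, fn, fp)
        assert acc == acc_swapped

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.tuples(*[st.integers(0, 50)] * 4))
    def test_bounds_and_harmonic_identity(self, counts):
        tp, tn, fp, fn = counts
        if tp + tn + fp + fn == 0:
            return
        acc, prec, rec, f1 = evaluate_metrics(tp, tn, fp, fn)
        for v in (acc, prec, rec, f1):
            assert 0.0 <= v <= 1.0
        assert f1 <= max(prec, rec) + 1e-12
        if prec + rec > 0:
            assert f1 == pytest.approx(2 * prec * rec / (prec + rec), abs=1e-12)


class TestConfusion:
    def test_identity_and_antidiagonal(self):
        y = np.array([0, 0, 1, 1])
        np.testing.assert_array_equal(confusion_matrix_normalized(y, y),
                                      np.eye(2))
        np.testing.assert_array_equal(confusion_matrix_normalized(y, 1 - y),
                                      np.eye(2)[::-1])

    def test_single_misread(self):
        truth = np.array([0] * 10 + [1] * 10)
        pred = truth.copy()
        pred[0] = 1
        mat = confusion_matrix_normalized(truth, pred)
        np.testing.assert_allclose(mat, [[0.9, 0.1], [0.0, 1.0]])
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix_normalized([], [])


class TestTraining:
    def test_separable_blobs_fit_perfectly(self):
        table = synthetic_feature_table(30, separation=10.0, seed=1)
        X = table[[c for c in table.columns
                   if c not in ("label", "animal_id")]].to_numpy()
        y = table["label"].to_numpy()
        for spec in default_specs().values():
            model = train_classifier(table, spec)
            assert (model.predict(X) == y).all(), spec.name

    def test_single_class_rejected(self):
        table = synthetic_feature_table(20, separation=1.0)
        with pytest.raises(ValueError):
            train_classifier(table[table["label"] == 1], default_specs()["lr"])

    def test_gaussian_nb_boundary_at_midpoint_of_symmetric_classes(self):
        # equal priors, mirrored samples -> exactly equal fitted variances,
        # so the 1-D decision boundary sits at the midpoint of the means
        rng = np.random.default_rng(0)
        pos = rng.normal(1.0, 0.5, 200)
        X = np.concatenate([-pos, pos])[:, None]
        y = np.repeat([0, 1], 200)
        est = build_estimator(default_specs()["gaussian_nb"], len(y))
        est.fit(X, y)
        lo, hi = -1.0, 1.0
        for _ in range(60):  # bisection on the predicted class
            mid = (lo + hi) / 2
            if est.predict([[mid]])[0] == 0:
                lo = mid
            else:
                hi = mid
        assert abs((lo + hi) / 2) < 1e-6

    def test_lr_threshold_consistent_with_probability(self):
        table = synthetic_feature_table(50, separation=1.0, seed=3)
        model = train_classifier(table, default_specs()["lr"])
        X = table[[c for c in table.columns
                   if c not in ("label", "animal_id")]].to_numpy()
        p = model.pipeline.predict_proba(X)[:, 1]
        np.testing.assert_array_equal(model.predict(X), (p >= 0.5).astype(int))


class TestCrossValidation:
    def test_noise_labels_score_at_chance(self):
        table = synthetic_feature_table(500, separation=0.0, seed=5)
        report = cross_validate(table, default_specs()["lr"], seed=5)
        assert 0.42 <= report.mean_metrics["accuracy"] <= 0.58

    def test_deterministic_given_seed(self, small_dataset):
        spec = default_specs()["svm_linear"]
        a = cross_validate(small_dataset, spec, seed=11)
        b = cross_validate(small_dataset, spec, seed=11)
        assert a.counts == b.counts
        np.testing.assert_array_equal(a.confusion, b.confusion)
        assert a.fold_metrics.equals(b.fold_metrics)

    def test_duplicated_table_scores_similarly(self, small_dataset):
        import pandas as pd
        spec = default_specs()["gaussian_nb"]
        single = cross_validate(small_dataset, spec, seed=1)
        doubled = cross_validate(
            pd.concat([small_dataset, small_dataset], ignore_index=True),
            spec, seed=1)
        assert abs(single.mean_metrics["accuracy"]
                   - doubled.mean_metrics["accuracy"]) < 0.05

    def test_small_class_rejected_with_class_name(self):
        table = synthetic_feature_table(30, separation=1.0)
        skewed = table[table["label"] == 1].head(5)
        bad = __import__("pandas").concat(
            [table[table["label"] == 0], skewed], ignore_index=True)
        with pytest.raises(ValueError, match="class 1"):
            cross_validate(bad, default_specs()["lr"])

    def test_confusion_rows_sum_to_one(self, small_dataset):
        report = cross_validate(small_dataset, default_specs()["knn"], seed=2)
        np.testing.assert_allclose(report.confusion.sum(axis=1), 1.0,
                                   atol=1e-9)


class TestSelection:
    @staticmethod
    def _report(name, f1, acc):
        import pandas as pd
        fold = pd.DataFrame({"accuracy": [acc], "precision": [f1],
                             "recall": [f1], "f1": [f1]})
        return ClassifierReport(spec=ClassifierSpec(name=name, family="lr"),
                                seed=0, k_folds=1, fold_metrics=fold,
                                confusion=np.eye(2), counts=(1, 1, 0, 0))

    def test_single_report_wins(self):
        r = self._report("lr", 0.9, 0.9)
        assert select_best([r]).name == "lr"

    def test_f1_tie_broken_by_accuracy(self):
        a = self._report("lr", 0.9, 0.91)
        b = self._report("knn", 0.9, 0.95)
        assert select_best([a, b]).name == "knn"

    def test_full_tie_broken_by_family_order(self):
        a = self._report("svm_rbf", 0.9, 0.9)
        b = self._report("gaussian_nb", 0.9, 0.9)
        assert select_best([a, b]).name == "gaussian_nb"

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_best([])
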