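"""Classifiers, balancing, metric arithmetic, and CV bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painreact import (ClassifierSpec, UnsupportedTaskError, balance_classes,
                       compute_metrics, run_cv, train_adaboost, train_svm)
from painreact.classify_eval import _one_patient_out_splits


def binary_from_confusion(tp, fn, fp, tn):
    y_true = np.r_[np.ones(tp + fn), np.zeros(fp + tn)].astype(int)
    y_pred = np.r_[np.ones(tp), np.zeros(fn), np.ones(fp),
                   np.zeros(tn)].astype(int)
    return y_true, y_pred


class TestMetrics:
    def test_hand_arithmetic_oracle(self):
        y_true, y_pred = binary_from_confusion(tp=8, fn=2, fp=1, tn=9)
        m = compute_metrics(y_true, y_pred, positive_class=1)
        assert m.sensitivity == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.888889, abs=1e-4)
        assert m.specificity == pytest.approx(0.9)
        assert m.accuracy == pytest.approx(0.85)
        assert m.f1 == pytest.approx(0.842105, abs=1e-4)
        assert m.undefined == ()

    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        m = compute_metrics(y, y, positive_class=1)
        assert all(getattr(m, k) == 1.0 for k in
                   ("accuracy", "sensitivity", "precision", "specificity",
                    "f1"))

    def test_all_predicted_negative(self):
        y_true = np.array([1, 1, 0, 0])
        y_pred = np.zeros(4, dtype=int)
        m = compute_metrics(y_true, y_pred, positive_class=1)
        assert m.sensitivity == 0.0 and m.specificity == 1.0
        assert "precision" in m.undefined

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_metrics([0, 1], [0], positive_class=1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(1, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(1, 30))
    def test_f1_is_harmonic_mean(self, tp, fn, fp, tn):
        m = compute_metrics(*binary_from_confusion(tp, fn, fp, tn),
                            positive_class=1)
        if m.sensitivity + m.precision > 0:
            expected = (2 * m.sensitivity * m.precision
                        / (m.sensitivity + m.precision))
            assert m.f1 == pytest.approx(expected)


class TestBalancing:
    def labels(self, counts):
        return np.repeat(np.arange(len(counts)), counts)

    def test_undersamples_to_minority(self):
        y = self.labels([100, 40, 60])
        idx = balance_classes(y, seed=0)
        vals, counts = np.unique(y[idx], return_counts=True)
        assert np.array_equal(counts, [40, 40, 40])

    def test_already_balanced_keeps_counts(self):
        y = self.labels([30, 30])
        idx = balance_classes(y, seed=1)
        assert np.unique(y[idx], return_counts=True)[1].tolist() == [30, 30]

    def test_deterministic_per_seed(self):
        y = self.labels([50, 20, 35])
        assert np.array_equal(balance_classes(y, seed=7),
                              balance_classes(y, seed=7))

    def test_missing_class_named(self):
        y = self.labels([10, 10])
        with pytest.raises(ValueError, match="severe"):
            balance_classes(y, seed=0, classes=[0, 1, 2])


def blobs(n=200, sep=6.0, seed=0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.standard_normal((n // 2, 2)),
                   rng.standard_normal((n // 2, 2)) + sep])
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    return X, y


class TestAdaBoost:
    def test_separable_blobs_fit_perfectly(self):
        X, y = blobs()
        model = train_adaboost(X, y, seed=0)
        assert (model.predict(X) == y).mean() == 1.0

    def test_single_learner_is_one_tree(self):
        X, y = blobs()
        model = train_adaboost(X, y, ClassifierSpec(n_learners=1), seed=0)
        assert len(model.estimators_) == 1
        from sklearn.tree import DecisionTreeClassifier
        tree = DecisionTreeClassifier(max_leaf_nodes=21, random_state=0)
        tree.fit(X, y)
        assert np.array_equal(model.predict(X), tree.predict(X))

    def test_tree_depth_limited(self):
        X, y = blobs(n=400, sep=1.0)
        model = train_adaboost(X, y, ClassifierSpec(max_branch_nodes=20),
                               seed=0)
        for est in model.estimators_:
            assert est.get_n_leaves() <= 21

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(0)
        X, y = blobs(n=400, sep=6.0)
        y_perm = rng.permutation(y)
        model = train_adaboost(X[:300], y_perm[:300], seed=0)
        acc = (model.predict(X[300:]) == y_perm[300:]).mean()
        assert abs(acc - 0.5) < 0.15

    def test_single_class_rejected(self):
        X, _ = blobs()
        with pytest.raises(ValueError):
            train_adaboost(X, np.zeros(X.shape[0], dtype=int))

    def test_multiclass_supported(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.standard_normal((50, 2)) + off
                       for off in ((0, 0), (6, 0), (0, 6))])
        y = np.repeat([0, 1, 2], 50)
        model = train_adaboost(X, y, seed=0)
        assert (model.predict(X) == y).mean() > 0.98


class TestSVM:
    def xor(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(-1, 1, size=(n, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        return X, y

    def test_xor_with_rbf_kernel(self):
        X, y = self.xor()
        model = train_svm(X, y, ClassifierSpec(kind="svm", kernel_scale=0.3))
        assert (model.predict(X) == y).mean() > 0.95

    def test_duplicated_points_same_predictions(self):
        # duplicating every point doubles each point's loss weight, which is
        # the same model as the original data at twice the box constraint
        X, y = self.xor(80)
        a = train_svm(X, y, ClassifierSpec(kind="svm", kernel_scale=0.5,
                                           box_constraint=2.0))
        b = train_svm(np.vstack([X, X]), np.r_[y, y],
                      ClassifierSpec(kind="svm", kernel_scale=0.5,
                                     box_constraint=1.0))
        grid = np.random.default_rng(2).uniform(-1, 1, size=(50, 2))
        assert np.array_equal(a.predict(grid), b.predict(grid))

    def test_three_classes_rejected(self):
        X = np.random.default_rng(0).standard_normal((30, 2))
        y = np.repeat([0, 1, 2], 10)
        with pytest.raises(UnsupportedTaskError):
            train_svm(X, y)


def toy_dataset(n_subjects=4, frames_per=60, seed=0):
    """Separable 3-class frames spread over subjects."""
    rng = np.random.default_rng(seed)
    X, y, subj = [], [], []
    for s in range(n_subjects):
        for cls, off in enumerate(((0, 0), (5, 0), (0, 5))):
            pts = rng.standard_normal((frames_per // 3, 2)) * 0.7 + off
            X.append(pts)
            y.extend([cls] * pts.shape[0])
            subj.extend([f"S{s}"] * pts.shape[0])
    return np.vstack(X), np.asarray(y), np.asarray(subj)


class TestRunCV:
    def test_kfold_bookkeeping(self):
        X, y, subj = toy_dataset()
        res = run_cv(X, y, subj, "multiclass", "kfold10", runs=2, seed=0)
        assert res.n_evaluations == 20
        assert set(res.raw) == {"no_pain", "moderate_pain", "severe_pain"}
        assert res.macro_f1() > 0.9

    def test_one_patient_out_counts(self):
        X, y, subj = toy_dataset(n_subjects=5)
        res = run_cv(X, y, subj, "multiclass", "one_patient_out", runs=2,
                     seed=0)
        assert res.n_evaluations == 10  # 5 subjects x 2 runs

    def test_one_patient_out_no_leakage(self):
        X, y, subj = toy_dataset(n_subjects=4)
        rng = np.random.default_rng(0)
        for train_idx, test_idx in _one_patient_out_splits(
                y, subj, [0, 1, 2], rng):
            assert set(subj[train_idx]).isdisjoint(set(subj[test_idx]))
            vals, counts = np.unique(y[train_idx], return_counts=True)
            assert counts.min() == counts.max()  # balanced training split

    def test_binary_task_filters_classes(self):
        X, y, subj = toy_dataset()
        res = run_cv(X, y, subj, "sev_vs_no", "kfold10", runs=1, seed=0)
        assert list(res.raw) == ["severe_pain"]
        assert res.mean("severe_pain", "f1") > 0.9

    def test_svm_multiclass_rejected(self):
        X, y, subj = toy_dataset()
        with pytest.raises(UnsupportedTaskError):
            run_cv(X, y, subj, "multiclass", "kfold10",
                   ClassifierSpec(kind="svm"), runs=1, seed=0)

    def test_single_subject_loso_rejected(self):
        X, y, subj = toy_dataset(n_subjects=1)
        with pytest.raises(ValueError):
            run_cv(X, y, subj, "multiclass", "one_patient_out", runs=1,
                   seed=0)

    def test_subject_missing_class_is_skipped(self, caplog):
        X, y, subj = toy_dataset(n_subjects=3)
        # subject S2 loses all severe frames
        keep = ~((subj == "S2") & (y == 2))
        res = run_cv(X[keep], y[keep], subj[keep], "multiclass",
                     "one_patient_out", runs=1, seed=0)
        assert res.n_evaluations == 2

    def test_reproducible_per_seed(self):
        X, y, subj = toy_dataset()
        a = run_cv(X, y, subj, "multiclass", "kfold10", runs=1, seed=3)
        b = run_cv(X, y, subj, "multiclass", "kfold10", runs=1, seed=3)
        assert a.to_json() == b.to_json()
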