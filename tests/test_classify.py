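import numpy as np
import pandas as pd
import pytest

from cranioshape.classify import (
    CLASSIFIER_NAMES,
    CVPlan,
    FeatureTable,
    compute_report,
    cross_validate,
    make_cv_plan,
    sweep_components,
    train_predict,
)


def mirrored_table(rng, n_per_class=10, k=4, classes=("control", "coronal", "sagittal", "metopic")):
    """Feature table with well-separated class blobs plus mirrored twins."""
    alphas, labels = [], []
    for i, cls in enumerate(classes):
        center = np.zeros(k)
        center[i % k] = 8.0
        alphas.append(center + rng.normal(size=(n_per_class, k)))
        labels += [cls] * n_per_class
    alpha = np.vstack(alphas)
    n = len(alpha)
    # mirrors: slightly perturbed copies appended after the originals
    alpha_m = alpha + rng.normal(0, 0.01, alpha.shape)
    return FeatureTable(
        np.vstack([alpha, alpha_m]),
        np.array(labels * 2),
        np.concatenate([np.zeros(n, bool), np.ones(n, bool)]),
        np.concatenate([np.full(n, -1), np.arange(n)]).astype(np.int64),
    )


class TestCVPlan:
    def test_one_test_sample_per_fold(self):
        rng = np.random.default_rng(0)
        t = mirrored_table(rng, n_per_class=5, classes=("a", "b"))
        plan = make_cv_plan(t, n_folds=5, seed=0)
        for fold in plan.test_folds:
            assert len(fold) == 2  # one per class

    def test_stratification_balanced(self):
        rng = np.random.default_rng(1)
        t = mirrored_table(rng, n_per_class=10)
        plan = make_cv_plan(t, n_folds=10, seed=0)
        for fold in plan.test_folds:
            labels = t.labels[fold]
            vals, counts = np.unique(labels, return_counts=True)
            assert len(vals) == 4 and (counts == 1).all()

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_partition_and_mirror_exclusion(self, seed):
        rng = np.random.default_rng(seed)
        t = mirrored_table(rng, n_per_class=12)
        plan = make_cv_plan(t, n_folds=10, seed=seed)
        plan.check_no_leakage(t)  # raises on violation
        all_test = np.concatenate(plan.test_folds)
        assert sorted(all_test) == sorted(t.original_ids)
        # mirrors of test originals never in that fold's training
        for test, train in zip(plan.test_folds, plan.train_folds):
            mirror_rows = [i for i in range(len(t.mirror_of)) if t.mirror_of[i] in test]
            assert not set(mirror_rows) & set(train)

    def test_leakage_detected(self):
        rng = np.random.default_rng(2)
        t = mirrored_table(rng, n_per_class=5, classes=("a", "b"))
        plan = make_cv_plan(t, n_folds=5, seed=0)
        bad = CVPlan(
            test_folds=list(plan.test_folds),
            train_folds=[np.concatenate([tr, [t.original_ids.size + te[0]]]) for tr, te in zip(plan.train_folds, plan.test_folds)],
        )
        with pytest.raises(AssertionError, match="mirror"):
            bad.check_no_leakage(t)

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(3)
        t = mirrored_table(rng)
        p1 = make_cv_plan(t, seed=5)
        p2 = make_cv_plan(t, seed=5)
        for a, b in zip(p1.test_folds, p2.test_folds):
            assert np.array_equal(a, b)

    def test_single_class_error(self):
        t = FeatureTable.from_alphas(np.zeros((10, 2)), np.array(["a"] * 10))
        with pytest.raises(ValueError, match="classes"):
            make_cv_plan(t)


class TestClassifiers:
    @pytest.mark.parametrize("name", CLASSIFIER_NAMES)
    def test_separable_blobs_perfect(self, name):
        rng = np.random.default_rng(4)
        train = FeatureTable.from_alphas(
            np.vstack([rng.normal(0, 0.5, (20, 2)), rng.normal(10, 0.5, (20, 2))]),
            np.array(["a"] * 20 + ["b"] * 20),
        )
        test = FeatureTable.from_alphas(
            np.vstack([rng.normal(0, 0.5, (10, 2)), rng.normal(10, 0.5, (10, 2))]),
            np.array(["a"] * 10 + ["b"] * 10),
        )
        pred = train_predict(name, train, test)
        assert (pred == test.labels).all()

    def test_lda_1d_boundary_at_midpoint(self):
        """Equal priors, shared variance: LDA boundary is the midpoint
        of the class means."""
        rng = np.random.default_rng(5)
        a = rng.normal(0.0, 1.0, 200)
        b = rng.normal(6.0, 1.0, 200)
        train = FeatureTable.from_alphas(
            np.concatenate([a, b])[:, None], np.array(["lo"] * 200 + ["hi"] * 200)
        )
        mid = (a.mean() + b.mean()) / 2
        eps = 1e-6
        test = FeatureTable.from_alphas(
            np.array([[mid - eps], [mid + eps]]), np.array(["lo", "hi"])
        )
        pred = train_predict("lda", train, test)
        assert pred[0] == "lo" and pred[1] == "hi"

    def test_knn_tie_broken_by_nearest(self):
        """Engineered 2-2-1 vote at k=5: the tie between two classes is
        resolved by the single nearest neighbour among the tied ones."""
        X = np.array([[1.0], [1.2], [2.0], [2.1], [3.0]])
        y = np.array(["b", "b", "a", "a", "c"])  # 2 b's, 2 a's, 1 c
        train = FeatureTable.from_alphas(X, y)
        test = FeatureTable.from_alphas(np.array([[1.1]]), np.array(["b"]))
        # neighbours of 1.1: all five; votes a=2, b=2 tie, c=1;
        # nearest among tied classes is 1.2 -> class b
        pred = train_predict("knn", train, test)
        assert pred[0] == "b"

    def test_unknown_classifier(self):
        t = FeatureTable.from_alphas(np.zeros((2, 1)), np.array(["a", "b"]))
        with pytest.raises(ValueError, match="unknown"):
            train_predict("mlp", t, t)


class TestSweep:
    def test_signal_in_first_component(self):
        rng = np.random.default_rng(6)
        n = 40
        labels = np.array(["a"] * (n // 2) + ["b"] * (n // 2))
        alpha = rng.normal(size=(n, 6)) * 0.3
        alpha[:, 0] += np.where(labels == "a", -5.0, 5.0)
        t = FeatureTable.from_alphas(alpha, labels)
        plan = make_cv_plan(t, n_folds=10, seed=0)
        accs, chosen = sweep_components(t, plan, "lda", k_max=6, seed=0)
        assert chosen == 1
        assert accs[0] == 1.0

    def test_sweep_deterministic(self):
        rng = np.random.default_rng(7)
        t = mirrored_table(rng, n_per_class=10)
        plan = make_cv_plan(t, seed=1)
        a1, k1 = sweep_components(t, plan, "lda", k_max=4, seed=1)
        a2, k2 = sweep_components(t, plan, "lda", k_max=4, seed=1)
        assert k1 == k2 and np.array_equal(a1, a2)


class TestReport:
    def test_clinical_cohort_counts(self):
        """Confusion matrix of a 367-subject cohort (178 controls, 22
        coronal, 56 metopic, 111 sagittal) and its summary metrics."""
        C = np.array(
            [
                [178, 0, 0, 0],
                [5, 17, 0, 0],
                [0, 0, 56, 0],
                [3, 0, 0, 108],
            ]
        )
        rep = compute_report(C, class_names=["control", "coronal", "metopic", "sagittal"])
        assert round(rep.accuracy, 3) == 0.978
        assert round(rep.g_mean, 3) == 0.931
        assert round(rep.sensitivity["coronal"], 3) == 0.773
        assert round(rep.sensitivity["sagittal"], 3) == 0.973
        assert round(rep.specificity["control"], 3) == 0.958
        assert round(rep.sensitivity["control"], 3) == 1.0
        assert round(rep.specificity["coronal"], 3) == 1.0

    def test_perfect_diagonal(self):
        rep = compute_report(np.diag([5, 3, 2]))
        assert rep.accuracy == 1.0 and rep.g_mean == 1.0
        assert all(v == 1.0 for v in rep.sensitivity.values())
        assert all(v == 1.0 for v in rep.specificity.values())

    def test_uniform_2x2(self):
        rep = compute_report(np.array([[1, 1], [1, 1]]))
        assert rep.accuracy == 0.5 and rep.g_mean == 0.5
        assert all(v == 0.5 for v in rep.sensitivity.values())

    def test_empty_row_warns_nan(self):
        with pytest.warns(UserWarning, match="no true samples"):
            rep = compute_report(np.array([[0, 0], [1, 1]]))
        assert np.isnan(rep.sensitivity["class0"])

    def test_invalid_matrices(self):
        with pytest.raises(ValueError):
            compute_report(np.ones((2, 3)))
        with pytest.raises(ValueError):
            compute_report(np.array([[1.5, 0], [0, 1]]))

    def test_summary_smoke(self):
        rep = compute_report(np.diag([5, 3]), class_names=["x", "y"])
        s = rep.summary()
        assert "total accuracy" in s and "g-mean" in s


def test_cross_validate_pooled_total():
    rng = np.random.default_rng(8)
    t = mirrored_table(rng, n_per_class=10)
    plan = make_cv_plan(t, seed=0)
    C, y_true, y_pred = cross_validate(t, plan, "lda", 4)
    assert C.to_numpy().sum() == len(t.original_ids)
    assert len(y_true) == len(t.original_ids)
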