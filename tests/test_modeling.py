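"""Classifier registry, metric identities, the comparison grid and k-fold CV."""

import numpy as np
import pytest
from sklearn.dummy import DummyClassifier
from sklearn.metrics import average_precision_score

from sanqigrade import (REGISTRY, LabeledDataset, ModelSpec, average_precision,
                        compute_metrics, evaluate_once, kfold_cv, run_grid,
                        train_model, variability)
from sanqigrade.dataset import stratified_split
from sanqigrade.modeling import AlgorithmEntry


def toy_dataset(n_per_class=20, n_classes=2, n_features=6, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        X.append(rng.normal(loc=c * sep, size=(n_per_class, n_features)))
        y.extend([c + 1] * n_per_class)
    return LabeledDataset(np.vstack(X), np.array(y),
                          tuple(f"f{i}" for i in range(n_features)))


class TestTrainModel:
    def test_separable_data_fits_perfectly(self):
        ds = toy_dataset(sep=6.0)
        model = train_model(ModelSpec("extra_trees", seed=0), ds)
        assert np.mean(model.predict(ds.X) == ds.y) == 1.0

    def test_deterministic_under_seed(self):
        ds = toy_dataset(sep=1.0, seed=4)
        a = train_model(ModelSpec("lightgbm", seed=3), ds).predict(ds.X)
        b = train_model(ModelSpec("lightgbm", seed=3), ds).predict(ds.X)
        np.testing.assert_array_equal(a, b)

    def test_single_class_rejected(self):
        ds = toy_dataset(n_classes=1)
        with pytest.raises(ValueError, match="single class"):
            train_model(ModelSpec("random_forest"), ds)

    def test_every_registered_algorithm_trains(self):
        ds = toy_dataset(n_per_class=15, sep=4.0)
        for algo in REGISTRY:
            spec = ModelSpec(algo, hyperparameters={"iterations": 20}, seed=0)
            model = train_model(spec, ds)
            scores = model.predict_scores(ds.X)
            assert scores.shape == (len(ds), 2)
            np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-6)

    def test_label_shuffle_drops_to_chance(self):
        rng = np.random.default_rng(0)
        ds = toy_dataset(n_per_class=30, sep=0.0, seed=5)  # no signal at all
        accs = []
        for _ in range(20):
            y = rng.permutation(ds.y)
            shuffled = LabeledDataset(ds.X, y, ds.feature_names)
            train, test = stratified_split(shuffled, 0.8, seed=1)
            model = train_model(ModelSpec("extra_trees",
                                          {"iterations": 50}, seed=0), train)
            accs.append(np.mean(model.predict(test.X) == test.y))
        # chance = 1/2; 20-run mean should sit within ~4 SE of it
        assert abs(np.mean(accs) - 0.5) < 0.13


class TestMetrics:
    def test_hand_computed_binary_confusion(self):
        # TP=3, FP=1, FN=1, TN=5 for the positive class
        y_true = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0])
        y_pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0])
        report = compute_metrics(y_true, y_pred)
        assert report.accuracy == pytest.approx(0.8)
        cm = report.confusion  # classes sorted: [0, 1]
        tp = cm[1, 1]; fp = cm[0, 1]; fn = cm[1, 0]; tn = cm[0, 0]
        assert (tp, fp, fn, tn) == (3, 1, 1, 5)
        prec = tp / (tp + fp); rec = tp / (tp + fn)
        assert prec == pytest.approx(0.75) and rec == pytest.approx(0.75)
        assert 2 * prec * rec / (prec + rec) == pytest.approx(0.75)

    def test_perfect_predictions(self):
        y = np.array([1, 2, 3, 1, 2, 3])
        scores = np.eye(3)[y - 1]
        report = compute_metrics(y, y, scores, classes=[1, 2, 3])
        assert report.accuracy == report.f1 == report.mAP == 1.0

    def test_all_wrong_binary(self):
        y = np.array([0, 1, 0, 1])
        report = compute_metrics(y, 1 - y)
        assert report.accuracy == 0.0

    def test_confusion_row_sums_are_class_counts(self, rng):
        y_true = rng.integers(0, 4, 60)
        y_pred = rng.integers(0, 4, 60)
        report = compute_metrics(y_true, y_pred, classes=range(4))
        np.testing.assert_array_equal(
            report.confusion.sum(axis=1),
            [np.sum(y_true == c) for c in range(4)])

    def test_macro_f1_invariant_to_relabeling(self, rng):
        y_true = rng.integers(0, 3, 50)
        y_pred = rng.integers(0, 3, 50)
        r1 = compute_metrics(y_true, y_pred, classes=[0, 1, 2])
        perm = {0: 2, 1: 0, 2: 1}
        map_ = np.vectorize(perm.get)
        r2 = compute_metrics(map_(y_true), map_(y_pred), classes=[0, 1, 2])
        assert r1.f1 == pytest.approx(r2.f1)

    def test_ap_matches_reference_on_untied_scores(self, rng):
        for _ in range(10):
            y = rng.integers(0, 2, 8).astype(bool)
            if not y.any():
                continue
            s = rng.permutation(np.linspace(0.1, 0.9, 8))  # no ties
            assert average_precision(y, s) == pytest.approx(
                average_precision_score(y, s))

    def test_ap_brute_force_recall_increments(self):
        # hand case: ranking (desc score) = [pos, neg, pos]; n_pos = 2
        y = np.array([1, 0, 1], dtype=bool)
        s = np.array([0.9, 0.8, 0.7])
        # AP = 1/2 * (P@1 + P@3) = 1/2 * (1 + 2/3)
        assert average_precision(y, s) == pytest.approx(5.0 / 6.0)

    def test_absent_class_excluded_from_map(self):
        y_true = np.array([0, 0, 1, 1])
        y_pred = np.array([0, 1, 1, 1])
        scores = np.random.default_rng(0).random((4, 3))
        with pytest.warns(UserWarning, match="absent"):
            report = compute_metrics(y_true, y_pred, scores, classes=[0, 1, 2])
        assert np.isnan(report.per_class_AP[2])
        assert not np.isnan(report.mAP)


class TestVariability:
    def test_hand_computed_two_values(self):
        assert variability([0.8, 1.0]) == pytest.approx(np.sqrt(0.02))

    def test_constant_runs_have_zero_spread(self):
        assert variability([0.9, 0.9, 0.9]) == 0.0

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            variability([0.5])


class TestGrid:
    def test_single_cell_matches_direct_evaluation(self):
        ds = toy_dataset(n_per_class=25, sep=2.0, seed=2)
        grid = run_grid({2: ds}, feature_sets=("ALL",),
                        algorithms=("extra_trees",), seed=9)
        assert len(grid) == 1
        train, test = stratified_split(ds, 0.8, seed=9)
        report = evaluate_once(ModelSpec("extra_trees", seed=9), train, test,
                               feature_set="ALL", seed=9)
        assert grid.iloc[0]["accuracy"] == pytest.approx(report.accuracy)

    def test_row_count_is_full_cross_product(self):
        ds = toy_dataset(n_per_class=15, sep=3.0)
        grid = run_grid({2: ds, 3: ds}, feature_sets=("ALL", "COR"),
                        algorithms=("extra_trees", "random_forest"), seed=0)
        assert len(grid) == 2 * 2 * 2

    def test_failed_cell_recorded_not_fatal(self):
        ds = toy_dataset(n_per_class=15)
        grid = run_grid({2: ds}, feature_sets=("ALL", "BOGUS"),
                        algorithms=("extra_trees",), seed=0)
        bad = grid[grid["feature_set"] == "BOGUS"]
        assert len(bad) == 1 and bad.iloc[0]["error"] != ""
        assert (grid[grid["feature_set"] == "ALL"]["error"] == "").all()


class TestKfoldCv:
    def test_majority_predictor_scores_prevalence(self):
        REGISTRY["_dummy"] = AlgorithmEntry(
            lambda **kw: DummyClassifier(strategy="most_frequent"), {}, {})
        try:
            ds = toy_dataset(n_per_class=20, seed=1)
            ds = ds.subset(np.arange(30))  # classes 20 / 10
            reports, summary = kfold_cv(ModelSpec("_dummy"), ds, k=5, seed=0,
                                        smote_target=1)  # disable balancing
            assert summary["accuracy"]["mean"] == pytest.approx(20 / 30, abs=1e-9)
        finally:
            del REGISTRY["_dummy"]

    def test_fold_assignment_deterministic(self):
        ds = toy_dataset(n_per_class=15, sep=2.0, seed=3)
        _, s1 = kfold_cv(ModelSpec("extra_trees", {"iterations": 30}), ds,
                         k=3, seed=5)
        _, s2 = kfold_cv(ModelSpec("extra_trees", {"iterations": 30}), ds,
                         k=3, seed=5)
        assert s1 == s2

    def test_k_larger_than_n_rejected(self):
        ds = toy_dataset(n_per_class=3)
        with pytest.raises(ValueError):
            kfold_cv(ModelSpec("extra_trees"), ds, k=10)

    def test_balance_then_split_compat_mode_runs(self):
        ds = toy_dataset(n_per_class=12, sep=3.0, seed=6)
        ds = ds.subset(np.arange(20))  # unbalanced 12 / 8
        reports, summary = kfold_cv(
            ModelSpec("extra_trees", {"iterations": 30}), ds, k=3, seed=0,
            smote_inside_folds=False)
        assert len(reports) == 3
        assert 0.0 <= summary["accuracy"]["mean"] <= 1.0
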