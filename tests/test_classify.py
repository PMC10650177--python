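"""Classifiers, splitting, evaluation and the benchmark harness."""

import numpy as np
import pandas as pd
import pytest

from periemg.classify import (
    BpnnModel,
    DivergenceError,
    SplitSpec,
    evaluate,
    kkt_audit,
    majority_vote,
    run_benchmark,
    split,
    task_labels,
    train_bpnn,
    train_random_forest,
    train_svm,
)


def blobs(rng, centers, n_per_class, spread=0.1):
    X, y = [], []
    for label, center in enumerate(centers):
        X.append(center + spread * rng.standard_normal((n_per_class, len(center))))
        y.extend([label] * n_per_class)
    return np.vstack(X), np.array(y)


class TestSvm:
    def test_separable_blobs_perfect_accuracy_and_feasible_dual(self, rng):
        X, y = blobs(rng, [(-3, -3), (3, 3)], 40)
        X_tr, X_te, y_tr, y_te = split(X, y, SplitSpec(seed=1))
        model = train_svm(X_tr, y_tr, C=1.0)
        assert evaluate(model, X_te, y_te).accuracy == 1.0
        audit = kkt_audit(model)
        assert audit["max_bound_violation"] <= 1e-6
        assert audit["max_balance_violation"] <= 1e-6
        assert audit["feasible"] == 1.0

    def test_single_point_per_class_memorized(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array(["a", "b"])
        model = train_svm(X, y)
        assert list(model.predict(X)) == ["a", "b"]

    def test_own_decision_function_matches_reference_solver(self, rng):
        """Dual route: our kernel-expansion decision values must agree with
        the solver's own decision function on each binary subproblem."""
        from sklearn.svm import SVC

        X, y = blobs(rng, [(-2, 0), (2, 0), (0, 3)], 30, spread=0.8)
        model = train_svm(X, y, C=1.0)
        Xs = model.scaler.transform(X)
        scores = model.decision_function(X)
        for m, cls in enumerate(model.classes):
            ref = SVC(C=1.0, kernel="rbf", gamma=model.gamma)
            ref.fit(Xs, np.where(y == cls, 1.0, -1.0))
            np.testing.assert_allclose(
                scores[:, m], ref.decision_function(Xs), atol=1e-8
            )

    def test_single_class_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            train_svm(X, np.zeros(10))

    def test_non_finite_features_rejected(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError):
            train_svm(X, np.array([0, 1]))


class TestRandomForest:
    def test_fully_grown_forest_memorizes_training_points(self, rng):
        X, y = blobs(rng, [(-2, -2), (2, 2), (2, -2)], 20)
        model = train_random_forest(X, y, n_trees=50, seed=0)
        assert np.array_equal(model.predict(X), y)
        assert evaluate(model, X, y).accuracy == 1.0  # leakage sanity check

    def test_single_tree_forest_equals_its_tree(self, rng):
        X, y = blobs(rng, [(-2, -2), (2, 2)], 25)
        model = train_random_forest(X, y, n_trees=1, seed=3)
        tree_pred = model.forest.estimators_[0].predict(X).astype(int)
        np.testing.assert_array_equal(model.predict(X), model.classes[tree_pred])

    def test_even_vote_breaks_to_lowest_class_index(self):
        votes = np.array([[0, 1, 2], [1, 1, 2], [0, 2, 1], [1, 2, 1]])  # trees x samples
        out = majority_vote(votes, n_classes=3)
        # sample 0: classes 0 and 1 tie at 2 votes -> class 0
        # sample 1: 1 and 2 tie -> class 1; sample 2: 1 and 2 tie -> class 1
        np.testing.assert_array_equal(out, [0, 1, 1])

    def test_seed_determinism(self, rng):
        X, y = blobs(rng, [(-1, -1), (1, 1)], 30, spread=0.8)
        m1 = train_random_forest(X, y, seed=5)
        m2 = train_random_forest(X, y, seed=5)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))


class TestBpnn:
    def xor_data(self, rng, n=50):
        centers = [(0, 0), (1, 1), (0, 1), (1, 0)]
        labels = [0, 0, 1, 1]
        X, y = [], []
        for c, lab in zip(centers, labels):
            X.append(c + 0.05 * rng.standard_normal((n, 2)))
            y.extend([lab] * n)
        return np.vstack(X), np.array(y)

    def test_xor_pattern_learned(self, rng):
        X, y = self.xor_data(rng)
        model = train_bpnn(X, y, hidden_sizes=(8,), epochs=2000, learning_rate=0.5, seed=1)
        assert np.mean(model.predict(X) == y) >= 0.95

    def test_zero_epochs_predicts_from_initialization(self, rng):
        X, y = self.xor_data(rng)
        model = train_bpnn(X, y, epochs=0, seed=2)
        preds = model.predict(X)
        assert preds.shape == y.shape
        assert set(preds) <= set(model.classes)
        assert model.loss_history.size == 1  # only the initial loss

    def test_loss_decreases_on_separable_data(self, rng):
        X, y = blobs(rng, [(-2, -2), (2, 2)], 40)
        model = train_bpnn(X, y, epochs=100, learning_rate=0.1, seed=0)
        assert model.loss_history[-1] < model.loss_history[0]

    def test_divergence_raises(self, rng):
        X, y = blobs(rng, [(-1, -1), (1, 1)], 20)
        with pytest.raises(DivergenceError):
            train_bpnn(X, y, epochs=50, learning_rate=1e150, seed=0)

    def test_seed_determinism(self, rng):
        X, y = self.xor_data(rng, n=20)
        m1 = train_bpnn(X, y, epochs=50, seed=9)
        m2 = train_bpnn(X, y, epochs=50, seed=9)
        np.testing.assert_array_equal(m1.loss_history, m2.loss_history)
        np.testing.assert_array_equal(m1.predict(X), m2.predict(X))


class TestSplit:
    def test_80_20_disjoint_exhaustive(self, rng):
        X = rng.standard_normal((100, 4))
        y = np.repeat(np.arange(5), 20)
        X_tr, X_te, y_tr, y_te = split(X, y, SplitSpec(seed=0))
        assert len(X_tr) == 80 and len(X_te) == 20
        all_rows = np.vstack([X_tr, X_te])
        assert np.array_equal(
            np.sort(all_rows, axis=0), np.sort(X, axis=0)
        )

    def test_stratification_preserves_proportions(self, rng):
        X = rng.standard_normal((100, 2))
        y = np.repeat(np.arange(5), 20)
        _, _, y_tr, y_te = split(X, y, SplitSpec(seed=1))
        for cls in range(5):
            assert abs(np.sum(y_te == cls) - 4) <= 1

    def test_same_seed_same_split(self, rng):
        X = rng.standard_normal((50, 2))
        y = np.repeat([0, 1], 25)
        a = split(X, y, SplitSpec(seed=3))
        b = split(X, y, SplitSpec(seed=3))
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[3], b[3])

    def test_singleton_class_rejected_when_stratified(self, rng):
        X = rng.standard_normal((5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError):
            split(X, y, SplitSpec())


class _ConstantModel:
    def __init__(self, classes, value):
        self.classes = np.asarray(classes)
        self.value = value

    def predict(self, X):
        return np.full(len(X), self.value)


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        X, y = blobs(rng, [(-3, -3), (3, 3)], 20)
        model = train_random_forest(X, y, n_trees=20, seed=0)
        report = evaluate(model, X, y)
        assert report.accuracy == report.recall == report.f1 == 1.0
        assert np.all(np.diag(report.confusion) == 20)

    def test_all_one_class_on_balanced_five_class(self):
        model = _ConstantModel(classes=np.arange(5), value=2)
        X = np.zeros((50, 2))
        y = np.repeat(np.arange(5), 10)
        report = evaluate(model, X, y)
        assert report.accuracy == pytest.approx(0.2)
        assert report.recall == pytest.approx(0.2)  # macro over 5 classes
        assert report.averaging == "macro"

    def test_confusion_matches_manual_count(self):
        model = _ConstantModel(classes=np.array(["a", "b"]), value="a")
        y = np.array(["a", "a", "b", "b", "b", "a", "b", "a", "a", "b"])
        report = evaluate(model, np.zeros((10, 1)), y)
        assert report.confusion.loc["a", "a"] == 5
        assert report.confusion.loc["b", "a"] == 5
        assert report.confusion.to_numpy().sum() == 10
        # Row sums equal per-class test counts.
        assert list(report.confusion.sum(axis=1)) == [5, 5]

    def test_unknown_test_label_rejected(self):
        model = _ConstantModel(classes=np.array(["a", "b"]), value="a")
        with pytest.raises(ValueError, match="vocabulary"):
            evaluate(model, np.zeros((2, 1)), np.array(["a", "z"]))


def synthetic_feature_frame(rng, reps=6):
    """Small, cleanly separable epoch feature table with action/intensity."""
    from periemg.simulate import ACTIONS, INTENSITIES

    rows = []
    for a_idx, action in enumerate(ACTIONS):
        for i_idx, intensity in enumerate(INTENSITIES):
            for _ in range(reps):
                base = np.zeros(16)
                base[a_idx * 3 : a_idx * 3 + 3] = 1.0 + i_idx
                rows.append(
                    dict(
                        {f"f{k}": base[k] + 0.05 * rng.standard_normal() for k in range(16)},
                        action=action,
                        intensity=intensity,
                    )
                )
    return pd.DataFrame(rows)


class TestBenchmark:
    def test_task_label_construction(self, rng):
        df = synthetic_feature_frame(rng)
        X5, y5 = task_labels(df, "five_class")
        assert len(X5) == 30 and set(y5) == {"CE", "PL", "RE", "LCM", "FR"}
        X10, y10 = task_labels(df, "ten_class")
        assert len(X10) == 60 and len(set(y10)) == 10

    def test_missing_intensity_rejected(self, rng):
        df = synthetic_feature_frame(rng)
        df = df[df["intensity"] == "normal"]
        with pytest.raises(ValueError):
            task_labels(df, "five_class")

    def test_benchmark_rows_and_determinism(self, rng):
        df = synthetic_feature_frame(rng)
        table1, reports1 = run_benchmark(df, "five_class", ("rf", "svm"), seed=4)
        table2, _ = run_benchmark(df, "five_class", ("rf", "svm"), seed=4)
        assert list(table1["classifier"]) == ["rf", "svm"]
        pd.testing.assert_frame_equal(table1, table2)
        assert set(reports1) == {"rf", "svm"}
        cm = reports1["rf"].confusion
        assert cm.to_numpy().sum() == len(task_labels(df, "five_class")[1]) * 0.2

    def test_separable_features_classified_correctly(self, rng):
        df = synthetic_feature_frame(rng, reps=10)
        table, _ = run_benchmark(df, "ten_class", ("rf",), seed=0)
        assert table["accuracy"].iloc[0] >= 0.9
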