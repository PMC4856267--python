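import numpy as np
import pytest

from cryptocad.classify import (
    CLASSES,
    EvalReport,
    MLPModel,
    TrainConfig,
    classify,
    evaluate,
    load_model,
    predict_proba,
    save_model,
    split_dataset,
    train,
)
from cryptocad.errors import ParameterError, TrainingError, ValidationError


def make_clusters(n=400, sep=3.0, seed=11, n_features=7):
    """Two Gaussian clusters `sep` standard deviations apart."""
    rng = np.random.default_rng(seed)
    half = n // 2
    a = rng.normal(0.0, 1.0, size=(half, n_features))
    b = rng.normal(sep, 1.0, size=(n - half, n_features))
    X = np.vstack([a, b])
    labels = ["normal"] * half + ["cancer"] * (n - half)
    perm = rng.permutation(n)
    return X[perm], [labels[i] for i in perm]


class TestSplit:
    def test_reproduces_725_155_155(self):
        s = split_dataset(1035, (0.70, 0.15, 0.15), seed=42)
        assert (len(s.train), len(s.validation), len(s.test)) == (725, 155, 155)

    def test_three_thirds(self):
        s = split_dataset(3, (1 / 3, 1 / 3, 1 / 3), seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (1, 1, 1)

    def test_largest_remainder_tie_break(self):
        # n=10: floors (7,1,1), remainders (0,.5,.5); the residual unit goes
        # to the earlier split in train/validation/test order
        s = split_dataset(10, (0.7, 0.15, 0.15), seed=0)
        assert (len(s.train), len(s.validation), len(s.test)) == (7, 2, 1)

    def test_disjoint_cover(self):
        s = split_dataset(101, seed=5)
        all_idx = np.concatenate([s.train, s.validation, s.test])
        assert sorted(all_idx) == list(range(101))

    def test_too_small(self):
        with pytest.raises(ParameterError):
            split_dataset(2)


@pytest.fixture(scope="module")
def separable_run():
    X, labels = make_clusters()
    split = split_dataset(len(X), seed=11)
    model, report = train(X, labels, split, seed=11)
    return X, labels, split, model, report


class TestTraining:
    def test_separable_clusters_low_test_error(self, separable_run):
        _, _, _, _, report = separable_run
        assert report.decision_accuracy_error["test"] <= 2.0

    def test_training_points_recovered(self, separable_run):
        X, labels, split, model, _ = separable_run
        P = predict_proba(model, X[split.train])
        pred = np.where(P[:, 1] >= P[:, 0], "cancer", "normal")
        true = np.array(labels)[split.train]
        assert np.mean(pred == true) >= 0.98

    def test_shuffled_labels_near_chance(self):
        X, labels = make_clusters()
        rng = np.random.default_rng(11)
        shuffled = [labels[i] for i in rng.permutation(len(labels))]
        split = split_dataset(len(X), seed=11)
        _, report = train(X, shuffled, split, seed=11)
        test_labels = np.array(shuffled)[split.test]
        minority = min(np.mean(test_labels == c) for c in CLASSES)
        baseline = 100.0 * minority
        assert abs(report.decision_accuracy_error["test"] - baseline) <= 10.0

    def test_determinism(self):
        X, labels = make_clusters(n=120)
        split = split_dataset(len(X), seed=3)
        m1, r1 = train(X, labels, split, seed=3)
        m2, r2 = train(X, labels, split, seed=3)
        assert np.array_equal(m1.W1, m2.W1) and np.array_equal(m1.W2, m2.W2)
        assert r1.cross_entropy == r2.cross_entropy
        assert r1.decision_accuracy_error == r2.decision_accuracy_error

    def test_no_leakage_from_validation_or_test(self):
        # permuting rows within the validation and test splits must leave the
        # trained weights untouched (standardization uses the training split
        # only; validation enters only through its permutation-invariant loss)
        X, labels = make_clusters(n=160, seed=4)
        split = split_dataset(len(X), seed=4)
        m1, _ = train(X, labels, split, seed=4)
        rng = np.random.default_rng(0)
        X2, labels2 = X.copy(), list(labels)
        for idx in (split.validation, split.test):
            perm = rng.permutation(idx)
            X2[idx] = X[perm]
            for i, j in zip(idx, perm):
                labels2[i] = labels[j]
        m2, _ = train(X2, labels2, split, seed=4)
        assert np.array_equal(m1.W1, m2.W1)
        assert np.array_equal(m1.W2, m2.W2)
        assert np.array_equal(m1.input_mean, m2.input_mean)

    def test_early_stopping_improves_on_initial_loss(self, separable_run):
        _, _, _, model, _ = separable_run
        losses = [t for _, t, _ in model.training_log]
        vals = [v for _, _, v in model.training_log]
        best_epoch = int(np.argmin(vals))
        assert losses[best_epoch] <= losses[0]
        assert vals[best_epoch] == min(vals)

    def test_single_class_train_split_rejected(self):
        X = np.random.default_rng(0).normal(size=(30, 7))
        labels = ["normal"] * 30
        split = split_dataset(30, seed=0)
        with pytest.raises(TrainingError):
            train(X, labels, split, seed=0)


def constant_probability_model(p_cancer: float) -> MLPModel:
    """Zero-weight network emitting the same probabilities for any input."""
    b2 = np.array([np.log(1 - p_cancer), np.log(p_cancer)])
    return MLPModel(
        W1=np.zeros((4, 7)), b1=np.zeros(4), W2=np.zeros((2, 4)), b2=b2,
        input_mean=np.zeros(7), input_sd=np.ones(7),
    )


class TestClassifyAndEvaluate:
    def test_probabilities_sum_to_one(self, separable_run):
        X, _, _, model, _ = separable_run
        P = predict_proba(model, X)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_symmetric_model_ties_to_cancer(self):
        model = MLPModel(
            W1=np.zeros((4, 7)), b1=np.zeros(4), W2=np.zeros((2, 4)), b2=np.zeros(2),
            input_mean=np.zeros(7), input_sd=np.ones(7),
        )
        label, probs = classify(model, np.zeros(7))
        assert np.allclose(probs, [0.5, 0.5])
        assert label == "cancer"

    def test_nonfinite_input_rejected(self, separable_run):
        _, _, _, model, _ = separable_run
        with pytest.raises(ValidationError):
            classify(model, np.array([1, 2, np.nan, 4, 5, 6, 7.0]))

    def test_uniform_predictions_give_ln2(self):
        model = constant_probability_model(0.5)
        X = np.zeros((12, 7))
        labels = ["normal"] * 6 + ["cancer"] * 6
        split = split_dataset(12, (1 / 3, 1 / 3, 1 / 3), seed=0)
        report = evaluate(model, X, labels, split)
        for name in ("training", "validation", "test"):
            assert report.cross_entropy[name] == pytest.approx(np.log(2), abs=1e-12)

    def test_hand_computed_cross_entropy(self):
        # constant p_cancer = 0.8 on labels [c, c, n, n]:
        # CE = -(ln .8 + ln .8 + ln .2 + ln .2)/4; error = 50%
        model = constant_probability_model(0.8)
        X = np.zeros((4, 7))
        labels = ["cancer", "cancer", "normal", "normal"]
        split = split_dataset(4, (0.5, 0.25, 0.25), seed=1)
        report = evaluate(model, X, labels, split)
        full = evaluate(
            model, X, labels,
            type(split)(train=np.arange(4), validation=np.arange(4), test=np.arange(4)),
        )
        expected = -(2 * np.log(0.8) + 2 * np.log(0.2)) / 4
        assert full.cross_entropy["training"] == pytest.approx(expected, abs=1e-12)
        assert full.decision_accuracy_error["training"] == 50.0
        assert np.array(full.confusion["training"]).sum() == 4
        assert isinstance(report, EvalReport)

    def test_empty_split_rejected(self):
        model = constant_probability_model(0.5)
        split = split_dataset(4, (0.5, 0.25, 0.25), seed=1)
        split.test = np.array([], dtype=int)
        with pytest.raises(ParameterError):
            evaluate(model, np.zeros((4, 7)), ["normal", "cancer"] * 2, split)


def test_model_json_round_trip(tmp_path, separable_run):
    X, _, _, model, _ = separable_run
    save_model(model, tmp_path / "m.json")
    back = load_model(tmp_path / "m.json")
    assert np.array_equal(back.W1, model.W1)
    assert np.array_equal(back.input_sd, model.input_sd)
    assert np.allclose(predict_proba(back, X[:5]), predict_proba(model, X[:5]))
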