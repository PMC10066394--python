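"""Classifier: splitting, oversampling, training, prediction, evaluation.

Unit tests use small hidden layers and toy data; the full-scale 210-512-3
recovery run lives with the end-to-end checks.
"""

import numpy as np
import pytest

from ratpsg import (
    ClassifierConfig,
    evaluate,
    oversample_training,
    predict,
    split_dataset,
    train,
)
from ratpsg.classifier import TrainedClassifier, _round_split_sizes
from ratpsg.core import NREM, REM, WAKE, ValidationError
from ratpsg.features import WindowSample


def make_samples(n, label_of=None, dim=210, seed=0, centers=None):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        lab = label_of(i) if label_of else None
        out.append(
            WindowSample(
                features=rng.normal(size=dim),
                center_epoch=centers[i] if centers is not None else i + 2,
                label=lab,
            )
        )
    return out


def cluster_samples(n_per_class, sep=30.0, dim=210, seed=0):
    """Three well-separated Gaussian clusters in feature space."""
    rng = np.random.default_rng(seed)
    means = np.zeros((3, dim))
    for c in range(3):
        means[c, c * 10 : c * 10 + 10] = sep
    out = []
    i = 0
    for c in range(3):
        for _ in range(n_per_class):
            out.append(
                WindowSample(
                    features=means[c] + rng.normal(size=dim),
                    center_epoch=i + 2,
                    label=c,
                )
            )
            i += 1
    return out


SMALL = ClassifierConfig(
    hidden_size=32, max_iterations=300, patience=20, batch_size=32,
    learning_rate=3e-3, seed=0,
)


class TestSplit:
    def test_1000_samples_give_640_160_200(self):
        samples = make_samples(1000)
        tr, va, te = split_dataset(samples, seed=1)
        assert (len(tr), len(va), len(te)) == (640, 160, 200)

    def test_labeled_1000_also_exact_with_round_classes(self):
        samples = make_samples(1000, label_of=lambda i: 0 if i < 500 else (1 if i < 800 else 2))
        tr, va, te = split_dataset(samples, seed=1)
        assert (len(tr), len(va), len(te)) == (640, 160, 200)

    def test_five_samples_remainder_to_train(self):
        assert _round_split_sizes(5, (0.64, 0.16, 0.20)) == (3, 1, 1)
        tr, va, te = split_dataset(make_samples(5), seed=0)
        assert (len(tr), len(va), len(te)) == (3, 1, 1)

    def test_partition_is_disjoint_and_exhaustive(self):
        samples = make_samples(503, label_of=lambda i: i % 3)
        tr, va, te = split_dataset(samples, seed=3)
        ids = [id(s) for part in (tr, va, te) for s in part]
        assert len(ids) == len(set(ids)) == 503

    def test_same_seed_identical_partition(self):
        samples = make_samples(200, label_of=lambda i: i % 3)
        a = split_dataset(samples, seed=7)
        b = split_dataset(samples, seed=7)
        for pa, pb in zip(a, b):
            assert [id(s) for s in pa] == [id(s) for s in pb]

    def test_stratification_preserves_proportions(self):
        samples = make_samples(1000, label_of=lambda i: 0 if i < 700 else (1 if i < 900 else 2))
        tr, va, te = split_dataset(samples, seed=0)
        for part in (tr, va, te):
            frac0 = np.mean([s.label == 0 for s in part])
            assert abs(frac0 - 0.7) < 0.02

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            split_dataset(make_samples(10), fractions=(0.5, 0.2, 0.2))


class TestOversample:
    def test_balances_to_majority(self):
        counts = {0: 800, 1: 150, 2: 50}
        samples = []
        for c, n in counts.items():
            samples.extend(make_samples(n, label_of=lambda i, c=c: c, seed=c))
        out = oversample_training(samples, seed=0)
        got = np.bincount([s.label for s in out])
        assert got.tolist() == [800, 800, 800]

    def test_balanced_input_unchanged(self):
        samples = make_samples(90, label_of=lambda i: i % 3)
        out = oversample_training(samples, seed=0)
        assert len(out) == 90 and set(map(id, out)) == set(map(id, samples))

    def test_resampled_objects_come_from_input(self):
        samples = make_samples(60, label_of=lambda i: 0 if i < 50 else 1)
        out = oversample_training(samples, seed=0)
        assert set(map(id, out)) <= set(map(id, samples))
        assert len(out) == 100

    def test_unlabeled_rejected(self):
        with pytest.raises(ValidationError, match="label"):
            oversample_training(make_samples(10), seed=0)


class TestTraining:
    def test_separable_clusters_reach_perfect_accuracy(self):
        samples = cluster_samples(60)
        tr, va, te = split_dataset(samples, seed=0)
        model = train(tr, va, SMALL)
        assert evaluate(model, te).accuracy == 1.0

    def test_shuffled_labels_give_chance_accuracy(self):
        """Random features, labels shuffled: accuracy ~ 1/3 on a balanced
        test set."""
        rng = np.random.default_rng(1)
        samples = make_samples(1200, label_of=lambda i: int(rng.integers(3)), seed=2)
        tr, va, te = split_dataset(samples, seed=1)
        model = train(tr, va, SMALL)
        acc = evaluate(model, te).accuracy
        assert abs(acc - 1 / 3) < 0.05

    def test_same_seed_identical_weights(self):
        samples = cluster_samples(30, seed=5)
        tr, va, _ = split_dataset(samples, seed=2)
        m1 = train(tr, va, SMALL)
        m2 = train(tr, va, SMALL)
        np.testing.assert_array_equal(m1.w_hidden, m2.w_hidden)
        np.testing.assert_array_equal(m1.w_out, m2.w_out)

    def test_patience_stops_before_max_iterations(self):
        samples = cluster_samples(40, seed=3)
        tr, va, _ = split_dataset(samples, seed=0)
        cfg = ClassifierConfig(
            hidden_size=16, max_iterations=2000, patience=3, batch_size=32,
            learning_rate=3e-3, seed=0,
        )
        model = train(tr, va, cfg)
        assert model.history["n_iterations"] < 2000

    def test_feature_length_mismatch_rejected(self):
        samples = cluster_samples(10, dim=50)
        tr, va, _ = split_dataset(samples, seed=0)
        with pytest.raises(ValidationError, match="features"):
            train(tr, va, SMALL)


@pytest.fixture(scope="module")
def toy_model():
    samples = cluster_samples(60, seed=4)
    tr, va, _ = split_dataset(samples, seed=0)
    return train(tr, va, SMALL)


class TestPredictEvaluate:
    def test_predict_assembles_epoch_hypnogram(self, toy_model):
        samples = cluster_samples(60, seed=8)
        n = len(samples)
        for i, s in enumerate(samples):
            s.center_epoch = i + 2
        hyp = predict(toy_model, samples, n_epochs=n + 4)
        assert hyp.n_epochs == n + 4
        # edge epochs inherit nearest window's label
        assert hyp.labels[0] == hyp.labels[1] == hyp.labels[2]
        assert hyp.labels[-1] == hyp.labels[-2] == hyp.labels[-3]

    def test_argmax_tie_takes_lowest_index(self):
        model = TrainedClassifier(
            w_hidden=np.zeros((4, 2)), b_hidden=np.zeros(2),
            w_out=np.zeros((2, 3)), b_out=np.zeros(3),
            scaler_mean=np.zeros(4), scaler_scale=np.ones(4),
            config=ClassifierConfig(input_size=4, hidden_size=2),
        )
        proba = model.predict_proba(np.zeros((1, 4)))
        np.testing.assert_allclose(proba, 1 / 3)
        assert model.predict_classes(np.zeros((1, 4)))[0] == 0

    def test_perfect_predictions_metrics(self, toy_model):
        samples = cluster_samples(30, seed=9)
        report = evaluate(toy_model, samples)
        assert report.accuracy == 1.0
        assert report.macro_f1 == 1.0
        np.testing.assert_array_equal(np.diag(report.confusion), [30, 30, 30])
        assert report.confusion.sum() == 90

    def test_all_wake_predictor_closed_form(self):
        """A constant-WAKE predictor on a 30/30/30 test set: accuracy 1/3,
        F1(WAKE) = 0.5, other F1 = 0."""
        model = TrainedClassifier(
            w_hidden=np.zeros((210, 2)), b_hidden=np.zeros(2),
            w_out=np.zeros((2, 3)), b_out=np.array([5.0, 0.0, 0.0]),
            scaler_mean=np.zeros(210), scaler_scale=np.ones(210),
            config=ClassifierConfig(hidden_size=2),
        )
        samples = make_samples(90, label_of=lambda i: i % 3)
        report = evaluate(model, samples)
        assert report.accuracy == pytest.approx(1 / 3)
        assert report.f1_per_class[WAKE] == pytest.approx(0.5)
        assert report.f1_per_class[NREM] == 0.0 and report.f1_per_class[REM] == 0.0
        np.testing.assert_array_equal(report.confusion.sum(axis=1), [30, 30, 30])

    def test_empty_test_set_rejected(self, toy_model):
        with pytest.raises(ValidationError, match="empty"):
            evaluate(toy_model, [])
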