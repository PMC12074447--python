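"""Classifier contracts: gradient correctness, learning sanity, determinism,
vote aggregation and thresholding."""

import numpy as np
import pytest

from fetalmotion.evaluation import auroc
from fetalmotion.models import (
    BiLSTMClassifier,
    BiLSTMSpec,
    CNNClassifier,
    CNNSpec,
    classify,
    train_bilstm,
    train_cnn,
    train_rf,
    vote_fraction,
)
from fetalmotion.models._nn import bce_with_logits
from fetalmotion.representations import compute_spectrogram

FS = 128.0


def _finite_difference_check(model, X, y, eps=1e-5):
    logits, cache = model.forward(X, train=False)
    _, dz = bce_with_logits(logits, y)
    grads = model.backward(cache, dz)
    worst = 0.0
    for pi, p in enumerate(model.params):
        flat = p.ravel()
        idxs = np.random.default_rng(pi).choice(
            flat.size, size=min(6, flat.size), replace=False
        )
        for i in idxs:
            old = flat[i]
            flat[i] = old + eps
            lp, _ = bce_with_logits(model.forward(X)[0], y)
            flat[i] = old - eps
            lm, _ = bce_with_logits(model.forward(X)[0], y)
            flat[i] = old
            num = (lp - lm) / (2 * eps)
            ana = grads[pi].ravel()[i]
            worst = max(worst, abs(num - ana) / max(abs(num), abs(ana), 1e-8))
    return worst


class TestGradients:
    def test_bilstm_backprop_matches_finite_differences(self, rng):
        m = BiLSTMClassifier(3, BiLSTMSpec(units=5), seed=0, dtype=np.float64)
        for p in m.params:
            p += rng.normal(0, 0.1, p.shape)
        X = rng.normal(size=(4, 7, 3))
        y = rng.integers(0, 2, 4)
        assert _finite_difference_check(m, X, y) < 1e-4

    def test_cnn_backprop_matches_finite_differences(self, rng):
        m = CNNClassifier(
            (8, 12, 2), CNNSpec(filters1=4, filters2=3, dense_units=5),
            seed=0, dtype=np.float64,
        )
        for p in m.params:
            p += rng.normal(0, 0.1, p.shape)
        X = rng.normal(size=(4, 8, 12, 2))
        y = rng.integers(0, 2, 4)
        assert _finite_difference_check(m, X, y) < 1e-4


class TestRandomForest:
    def _toy(self, rng, n=200, shift=10.0):
        y = rng.integers(0, 2, n)
        X = rng.normal(size=(n, 8))
        X[y == 1, 0] += shift  # separable by 10 sd on one feature
        return X, y

    def test_separable_training_f1(self, rng):
        X, y = self._toy(rng)
        Xv, yv = self._toy(rng, 80)
        model = train_rf(X, y, Xv, yv, search_budget=3, seed=0)
        pred = classify(model.predict_scores(X))
        tp = np.sum((pred == 1) & (y == 1))
        f1 = 2 * tp / (2 * tp + np.sum(pred != y))
        assert f1 >= 0.99

    def test_random_labels_chance_auroc(self, rng):
        X = rng.normal(size=(300, 8))
        y = rng.integers(0, 2, 300)
        Xv = rng.normal(size=(150, 8))
        yv = rng.integers(0, 2, 150)
        model = train_rf(X, y, Xv, yv, search_budget=2, seed=1)
        assert abs(auroc(yv, model.predict_scores(Xv))[0] - 0.5) < 0.1

    def test_deterministic_selection(self, rng):
        X, y = self._toy(rng)
        Xv, yv = self._toy(rng, 60)
        a = train_rf(X, y, Xv, yv, search_budget=4, seed=9)
        b = train_rf(X, y, Xv, yv, search_budget=4, seed=9)
        assert a.best_params == b.best_params

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(50, 4))
        with pytest.raises(ValueError, match="single class"):
            train_rf(X, np.zeros(50), X, np.zeros(50), search_budget=1, seed=0)

    def test_vote_fraction_is_tree_majority(self, rng):
        """Score equals the brute-force count of positive trees / n_trees."""
        from sklearn.ensemble import RandomForestClassifier

        X, y = self._toy(rng, 100, shift=2.0)
        clf = RandomForestClassifier(n_estimators=5, random_state=0).fit(X, y)
        scores = vote_fraction(clf, X)
        manual = np.zeros(len(X))
        for tree in clf.estimators_:
            manual += tree.predict(X)
        np.testing.assert_allclose(scores, manual / 5.0)
        assert set(np.round(scores * 5)) <= {0, 1, 2, 3, 4, 5}


def _burst_tensors(rng, n):
    """0.5 s windows; positives carry a 5 Hz burst on channel 0."""
    X = rng.normal(0, 1, (n, 64, 2)).astype(np.float32)
    y = rng.integers(0, 2, n)
    t = np.arange(64) / FS
    X[y == 1, :, 0] += 3 * np.sin(2 * np.pi * 5 * t).astype(np.float32)
    return X, y


class TestBiLSTM:
    def test_easy_task_auroc(self, rng):
        Xtr, ytr = _burst_tensors(rng, 160)
        Xva, yva = _burst_tensors(rng, 60)
        Xte, yte = _burst_tensors(rng, 60)
        model, _ = train_bilstm(
            Xtr, ytr, Xva, yva, BiLSTMSpec(max_epochs=10, patience=4), seed=0
        )
        assert auroc(yte, model.predict_scores(Xte))[0] > 0.9

    def test_zero_epoch_budget_constant_scores(self, rng):
        X, y = _burst_tensors(rng, 40)
        model, _ = train_bilstm(
            X, y, X, y, BiLSTMSpec(max_epochs=0), seed=0
        )
        scores = model.predict_scores(X)
        np.testing.assert_allclose(scores, 0.5)  # zero-initialized head
        assert auroc(y, scores)[0] == pytest.approx(0.5)

    def test_scores_in_unit_interval(self, rng):
        X, y = _burst_tensors(rng, 80)
        model, _ = train_bilstm(
            X, y, X, y, BiLSTMSpec(max_epochs=2), seed=0
        )
        s = model.predict_scores(100 * X)  # extreme inputs still bounded
        assert np.all((s >= 0) & (s <= 1))

    def test_deterministic_given_seed(self, rng):
        X, y = _burst_tensors(rng, 60)
        m1, _ = train_bilstm(X, y, X, y, BiLSTMSpec(max_epochs=2), seed=4)
        m2, _ = train_bilstm(X, y, X, y, BiLSTMSpec(max_epochs=2), seed=4)
        np.testing.assert_array_equal(m1.predict_scores(X), m2.predict_scores(X))

    def test_empty_validation_rejected(self, rng):
        X, y = _burst_tensors(rng, 20)
        with pytest.raises(ValueError, match="validation"):
            train_bilstm(X, y, X[:0], y[:0], BiLSTMSpec(max_epochs=1), seed=0)


class TestCNN:
    def test_parameter_count_formula(self):
        """The default architecture's size is a fixed, documented integer."""
        for c in (15, 30):
            model = CNNClassifier((9, 1009, c), seed=0)
            conv1 = 3 * 3 * c * 32 + 32
            conv2 = 3 * 3 * 32 * 16 + 16
            dense = (1 * 501 * 16) * 16 + 16
            head = 16 + 1
            assert model.n_params == conv1 + conv2 + dense + head
        again = CNNClassifier((9, 1009, 15), seed=99)
        assert again.n_params == CNNClassifier((9, 1009, 15), seed=0).n_params

    def test_easy_task_auroc(self, rng):
        t = np.arange(1024) / FS

        def make(n):
            y = rng.integers(0, 2, n)
            X = np.empty((n, 9, 1009, 1), np.float32)
            for i in range(n):
                sig = rng.normal(0, 1, 1024)
                if y[i]:
                    sig += 2 * np.sin(2 * np.pi * 5 * t)
                X[i] = compute_spectrogram(sig, FS)
            return X, y

        Xtr, ytr = make(70)
        Xva, yva = make(30)
        Xte, yte = make(30)
        model, _ = train_cnn(
            Xtr, ytr, Xva, yva,
            CNNSpec(max_epochs=6, patience=3, batch_size=16), seed=0,
        )
        assert auroc(yte, model.predict_scores(Xte))[0] > 0.9

    def test_wrong_shape_rejected(self, rng):
        model = CNNClassifier((9, 1009, 2), seed=0)
        with pytest.raises(ValueError, match="shape"):
            model.forward(rng.normal(size=(2, 9, 500, 2)))


class TestClassify:
    def test_basic_threshold(self):
        assert classify(np.array([0.7]), 0.5)[0] == 1
        assert classify(np.array([0.3]), 0.5)[0] == 0
        np.testing.assert_array_equal(classify(np.zeros(5), 0.9), 0)

    def test_monotone_nesting(self, rng):
        scores = rng.random(200)
        hi = set(np.flatnonzero(classify(scores, 0.9)))
        lo = set(np.flatnonzero(classify(scores, 0.1)))
        assert hi <= lo

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            classify(np.array([0.5]), 0.0)
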