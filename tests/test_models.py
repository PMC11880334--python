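import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from burnscope import (ModelSpec, TrainConfig, augment, build_model,
                       categorical_crossentropy, evaluate, kfold_split,
                       stratified_split, train)
from burnscope.errors import TrainingError, ValidationError
from burnscope.models import (RnnClassifier, metrics_from_confusion, one_hot,
                              softmax, weights_hash)


class TestStratifiedSplit:
    def test_reference_sizes_at_90(self):
        y = np.repeat([0, 1, 2], 30)
        assert stratified_split(y, seed=0).sizes() == (63, 14, 13)

    def test_sizes_at_20(self):
        y = np.repeat([0, 1], 10)
        assert stratified_split(y, seed=0).sizes() == (14, 3, 3)

    def test_degenerate_all_train(self):
        y = np.repeat([0, 1], 5)
        s = stratified_split(y, fractions=(1.0, 0.0, 0.0), seed=0)
        assert s.sizes() == (10, 0, 0)

    def test_partition_and_stratification(self, rng):
        y = rng.integers(0, 3, 60)
        while np.bincount(y, minlength=3).min() < 3:
            y = rng.integers(0, 3, 60)
        s = stratified_split(y, seed=3)
        allidx = np.sort(np.concatenate([s.train, s.val, s.test]))
        assert np.array_equal(allidx, np.arange(60))
        # per-class train counts within 1 of proportionality
        for c in range(3):
            nc = (y == c).sum()
            got = (y[s.train] == c).sum()
            assert abs(got - nc * len(s.train) / 60) < 1.0 + 1e-9

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(10, 500))
    def test_floor_round_rule_all_sizes(self, n):
        y = np.arange(n) % 3
        if np.bincount(y).min() < 3:
            return
        s = stratified_split(y, seed=1)
        n_train = int(np.floor(0.70 * n + 1e-9))
        n_val = int(np.floor(0.15 * n + 0.5 + 1e-9))
        assert s.sizes() == (n_train, n_val, n - n_train - n_val)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValidationError):
            stratified_split(np.array([0, 0, 0, 1, 1]))


class TestKfold:
    def test_partition_and_fold_sizes(self):
        y = np.repeat([0, 1, 2], 30)
        folds = kfold_split(y, k=5, seed=0)
        tests = [te for _, te in folds]
        assert all(len(te) == 18 for te in tests)
        assert np.array_equal(np.sort(np.concatenate(tests)), np.arange(90))

    def test_deterministic(self):
        y = np.repeat([0, 1], 20)
        a = kfold_split(y, k=4, seed=9)
        b = kfold_split(y, k=4, seed=9)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            assert np.array_equal(te1, te2)

    def test_k_too_large(self):
        with pytest.raises(ValidationError):
            kfold_split(np.array([0, 1]), k=5)


class TestAugment:
    def test_shape_preserved(self, rng):
        x = rng.uniform(0, 1, (24, 24, 3))
        for _ in range(10):
            assert augment(x, rng).shape == x.shape

    def test_identity_draw(self, rng):
        x = rng.uniform(0, 1, (16, 16, 3))
        out = augment(x, rng, rotation=0.0, brightness=0.0, zoom=0.0)
        # only flips remain possible; disable by exhausting them
        flips = [augment(x, np.random.default_rng(s), rotation=0.0,
                         brightness=0.0, zoom=0.0) for s in range(8)]
        assert any(np.array_equal(f, x) for f in flips)
        assert out.shape == x.shape

    def test_brightness_multiplicative(self):
        x = np.full((8, 8, 1), 100.0)
        rng = np.random.default_rng(0)

        class FixedRng:
            def uniform(self, a, b):
                return 1.2 if (a, b) == (0.8, 1.2) else 0.0 if a < 0 else 1.0

            def random(self):
                return 0.9  # no flips

        out = augment(x, FixedRng(), clip=(0.0, 255.0))
        assert np.allclose(out, 120.0)


class TestLossAndSoftmax:
    def test_perfect_prediction_zero_loss(self):
        y = one_hot(np.array([0, 1, 2]), 3)
        assert categorical_crossentropy(y, y) < 1e-10

    def test_uniform_predictor_ln3(self):
        y = one_hot(np.array([0, 1, 2, 0]), 3)
        p = np.full((4, 3), 1 / 3)
        assert abs(categorical_crossentropy(y, p) - np.log(3)) < 1e-12

    def test_loss_monotone_toward_truth(self):
        y = one_hot(np.array([0]), 3)
        worse = np.array([[0.2, 0.4, 0.4]])
        better = np.array([[0.6, 0.2, 0.2]])
        assert categorical_crossentropy(y, better) < categorical_crossentropy(y, worse)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            categorical_crossentropy(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_softmax_rows_normalized(self, rng):
        p = softmax(rng.normal(size=(5, 3)) * 10)
        assert np.allclose(p.sum(axis=1), 1.0)


class TestBuildModels:
    def test_cnn_forward_probabilities(self, rng):
        model = build_model(ModelSpec(kind="cnn", input_size=16), seed=0)
        p = model.predict_proba(np.zeros((2, 3, 16, 16)))
        assert p.shape == (2, 3)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_cnn_bad_input_size(self):
        with pytest.raises(ValidationError):
            build_model(ModelSpec(kind="cnn", input_size=20), seed=0)

    def test_rnn_zero_weights_zero_hidden(self):
        model = RnnClassifier(4, 8, 3, np.random.default_rng(0))
        for k in ("Wxh", "Whh", "bh"):
            model.params[k][:] = 0.0
        model.forward(np.ones((2, 5, 4)))
        assert not model._h.any()

    def test_fnn_single_neuron_weighted_sum(self):
        # z = w . x + b with w=(1,2), x=(3,4), b=1 -> 12
        model = build_model(ModelSpec(kind="fnn", feature_dim=2, fnn_hidden=(),
                                      n_classes=1), seed=0)
        dense = model.layers[0]
        dense.params["W"][:, 0] = [1.0, 2.0]
        dense.params["b"][0] = 1.0
        out = model.forward(np.array([[3.0, 4.0]]))
        assert out[0, 0] == 12.0


class TestTraining:
    def _toy(self, n=24, rng=None):
        rng = rng or np.random.default_rng(0)
        X = rng.normal(size=(n, 10))
        y = (X[:, 0] > 0).astype(int) + (X[:, 1] > 0).astype(int)
        return X, y

    def test_smoke_one_epoch(self):
        X, y = self._toy()
        model = build_model(ModelSpec(kind="fnn"), seed=0)
        hist = train(model, X, y, cfg=TrainConfig(epochs=1, seed=0, augment=False))
        assert len(hist.train_loss) == 1 and np.isfinite(hist.train_loss[0])

    def test_loss_decreases_over_training(self):
        X, y = self._toy(n=60)
        model = build_model(ModelSpec(kind="fnn"), seed=0)
        hist = train(model, X, y, cfg=TrainConfig(epochs=50, seed=0, augment=False),
                     standardize=True)
        assert hist.train_loss[-1] <= hist.train_loss[0]

    def test_identical_seeds_identical_weights(self):
        X, y = self._toy(n=32)
        hashes = []
        for _ in range(2):
            model = build_model(ModelSpec(kind="fnn"), seed=7)
            train(model, X, y, cfg=TrainConfig(epochs=3, seed=7, augment=False))
            hashes.append(weights_hash(model))
        assert hashes[0] == hashes[1]

    def test_divergence_reported_with_epoch(self):
        X, y = self._toy()
        model = build_model(ModelSpec(kind="fnn"), seed=0)
        model.layers[0].params["W"][:] = np.nan
        with pytest.raises(TrainingError, match="epoch 1"):
            train(model, X, y, cfg=TrainConfig(epochs=1, seed=0, augment=False))

    def test_rnn_trains_on_sequences(self, rng):
        X = rng.normal(size=(20, 6, 4))
        y = (X[:, :, 0].mean(axis=1) > 0).astype(int)
        model = build_model(ModelSpec(kind="rnn", rnn_features=4, rnn_hidden=8,
                                      n_classes=2), seed=0)
        hist = train(model, X, y, cfg=TrainConfig(epochs=30, seed=0, augment=False))
        assert hist.train_loss[-1] < hist.train_loss[0]


class TestEvaluate:
    def test_hand_confusion_matrix(self):
        cm = np.array([[10, 0, 0], [1, 8, 1], [0, 0, 10]])
        m = metrics_from_confusion(cm)
        assert abs(m.accuracy - 28 / 30) < 1e-12
        assert abs(m.recall[1] - 0.8) < 1e-12
        assert abs(m.precision[1] - 1.0) < 1e-12

    def test_perfect_predictions(self):
        m = metrics_from_confusion(np.diag([5, 5, 5]))
        assert m.accuracy == 1.0
        assert np.allclose(m.f1, 1.0)
        assert m.macro["f1"] == 1.0 and m.weighted["f1"] == 1.0

    def test_macro_f1_is_mean_of_per_class(self, rng):
        for _ in range(10):
            cm = rng.integers(0, 20, (3, 3))
            if cm.sum() == 0:
                continue
            m = metrics_from_confusion(cm)
            assert abs(m.macro["f1"] - m.f1.mean()) < 1e-12

    def test_absent_class_flagged_zero(self):
        cm = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]])
        m = metrics_from_confusion(cm)
        assert m.absent_classes == [2]
        assert m.f1[2] == 0.0

    def test_order_invariance(self, rng):
        class Stub:
            n_classes = 3

            def predict(self, X):
                return np.asarray(X[:, 0], dtype=int)

        X = np.column_stack([rng.integers(0, 3, 30), np.zeros(30)])
        y = rng.integers(0, 3, 30)
        m1 = evaluate(Stub(), X, y)
        perm = rng.permutation(30)
        m2 = evaluate(Stub(), X[perm], y[perm])
        assert m1.accuracy == m2.accuracy
        assert np.array_equal(m1.confusion, m2.confusion)
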