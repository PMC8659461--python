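"""Tests of the deep models: architecture censuses, gradient correctness,
training sanity on small separable data, and the hybrid pipelines."""

import numpy as np
import pytest

from gazeload.classifiers import CVScheme
from gazeload.deep import (
    AEConfig,
    CNN1D,
    CNNConfig,
    LSTMClassifier,
    LSTMConfig,
    ae_svm_hybrid,
    cnn_svm_hybrid,
    extract_cnn_features,
    prepare_raw_windows,
    train_cnn,
    train_lstm,
    train_stacked_ae,
)
from gazeload.deep._nn import (
    BatchNorm1D,
    Conv1D,
    Dense,
    MaxPool1D,
)
from gazeload.deep.lstm import _LSTMCell


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        old = x[i]
        x[i] = old + eps
        fp = f()
        x[i] = old - eps
        fm = f()
        x[i] = old
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestBackpropGradients:
    """Analytic gradients match central finite differences."""

    def check_layer(self, layer, x, train=True):
        rng = np.random.default_rng(0)
        R = rng.normal(size=layer.forward(x, train).shape)

        def loss():
            return float((layer.forward(x, train) * R).sum())

        layer.forward(x, train)
        dx = layer.backward(R)
        assert np.allclose(dx, numeric_grad(loss, x), atol=1e-4)
        for name, p in layer.params.items():
            assert np.allclose(
                layer.grads[name], numeric_grad(loss, p), atol=1e-4
            ), name

    def test_conv1d(self):
        rng = np.random.default_rng(1)
        self.check_layer(Conv1D(2, 3, 3, rng), rng.normal(size=(2, 8, 2)))

    def test_dense(self):
        rng = np.random.default_rng(2)
        self.check_layer(Dense(5, 3, rng), rng.normal(size=(4, 5)))

    def test_batchnorm(self):
        rng = np.random.default_rng(3)
        layer = BatchNorm1D(3)
        x = rng.normal(size=(3, 6, 3))
        R = rng.normal(size=(3, 6, 3))

        # freeze batch statistics side effects out of the numeric loss
        def loss():
            mom = layer.momentum
            layer.momentum = 1.0
            out = float((layer.forward(x, True) * R).sum())
            layer.momentum = mom
            return out

        layer.forward(x, True)
        dx = layer.backward(R)
        assert np.allclose(dx, numeric_grad(loss, x), atol=1e-4)

    def test_maxpool(self):
        rng = np.random.default_rng(4)
        self.check_layer(MaxPool1D(2), rng.normal(size=(2, 9, 3)))

    def test_lstm_cell(self):
        rng = np.random.default_rng(5)
        self.check_layer(_LSTMCell(2, 4, rng), rng.normal(size=(2, 6, 2)))


def toy_dataset(n=60, S=32, seed=0):
    """Separable toy: class 0 smooth oscillation, class 1 white noise."""
    rng = np.random.default_rng(seed)
    X = np.empty((n, S, 2))
    y = np.arange(n) % 2
    t = np.linspace(0, 4 * np.pi, S)
    for i in range(n):
        if y[i] == 0:
            phase = rng.uniform(0, 2 * np.pi)
            X[i, :, 0] = np.sin(t + phase) + 0.1 * rng.normal(size=S)
            X[i, :, 1] = np.cos(t + phase) + 0.1 * rng.normal(size=S)
        else:
            X[i] = rng.normal(size=(S, 2))
    return X, y


class TestCNN:
    def test_layer_census_is_sixteen(self):
        net = CNN1D(32, 2, CNNConfig())
        assert net.n_layers == 16
        names = net.layer_names
        assert names[0] == "input" and names[-1] == "output"
        assert sum(n.startswith("conv") for n in names) == 3
        assert sum(n.startswith("batchnorm") for n in names) == 3
        assert sum(n.startswith("relu") for n in names) == 3
        assert sum(n.startswith("maxpool") for n in names) == 3
        assert names[13] == "fully_connected"  # the 14th layer

    def test_constant_window_valid_probabilities(self):
        net = CNN1D(32, 2, CNNConfig(epochs=1))
        X = np.zeros((4, 32, 2))
        net.fit(X[:2], np.array([0, 1]))
        p = net.predict_proba(X)
        assert np.allclose(p.sum(axis=1), 1.0)
        assert np.all(p >= 0)

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            CNN1D(4, 2, CNNConfig(pool=2))

    def test_learns_separable_toy(self):
        X, y = toy_dataset()
        _, preds = train_cnn(
            X, y, CNNConfig(filters=(8, 16, 16), epochs=25, seed=0), CVScheme(k=3, seed=0)
        )
        assert preds.accuracy >= 0.85

    def test_feature_extraction_shape_and_determinism(self):
        X, y = toy_dataset(n=20)
        cfg = CNNConfig(fc_width=24, epochs=2, seed=1)
        model, _ = train_cnn(X, y, cfg, CVScheme(k=2, seed=0))
        feats = extract_cnn_features(model, X)
        assert feats.shape == (20, 24)
        two = extract_cnn_features(model, np.stack([X[0], X[0]]))
        assert np.array_equal(two[0], two[1])

    def test_untrained_model_rejected(self):
        net = CNN1D(32, 2, CNNConfig())
        with pytest.raises(ValueError):
            net.fc_features(np.zeros((2, 32, 2)))

    def test_hybrid_parity_with_end_to_end(self):
        """CNN+SVM on FC features is within 0.05 of the CNN itself."""
        X, y = toy_dataset()
        cfg = CNNConfig(filters=(8, 16, 16), epochs=25, seed=0)
        cv = CVScheme(k=3, seed=0)
        model, preds = train_cnn(X, y, cfg, cv)
        hybrid = cnn_svm_hybrid(model, X, y, cv)
        assert hybrid.accuracy >= preds.accuracy - 0.05


class TestLSTM:
    def test_layer_census_is_five(self):
        net = LSTMClassifier(2, LSTMConfig())
        assert net.n_layers == 5
        assert net.layer_names == [
            "sequence_input",
            "lstm",
            "fully_connected",
            "softmax",
            "output",
        ]

    def test_probabilities_sum_to_one(self):
        net = LSTMClassifier(2, LSTMConfig(hidden_units=8, epochs=1))
        X, y = toy_dataset(n=10)
        net.fit(X, y)
        p = net.predict_proba(X)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_learns_separable_toy(self):
        X, y = toy_dataset()
        _, preds = train_lstm(
            X, y, LSTMConfig(hidden_units=16, epochs=30, seed=0), CVScheme(k=3, seed=0)
        )
        assert preds.accuracy >= 0.80

    def test_permuted_labels_chance_level(self):
        X, y = toy_dataset(n=80)
        rng = np.random.default_rng(0)
        yp = rng.permutation(y)
        _, preds = train_lstm(
            X, yp, LSTMConfig(hidden_units=8, epochs=5, seed=0), CVScheme(k=3, seed=0)
        )
        assert 0.25 <= preds.accuracy <= 0.75  # chance on n = 80


class TestStackedAE:
    def test_dimension_cascade(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 300))
        ae, feats = train_stacked_ae(X, AEConfig(hidden1=100, hidden2=50, epochs=20))
        assert ae.stage1.encode(X).shape == (40, 100)
        assert feats.shape == (40, 50)

    def test_training_reduces_loss(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 120)) @ rng.normal(size=(120, 120)) * 0.1
        ae, _ = train_stacked_ae(X, AEConfig(epochs=60))
        for curve in ae.loss_curves:
            assert curve[-1] < curve[0]

    def test_hidden_not_smaller_than_input_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            train_stacked_ae(rng.normal(size=(30, 80)), AEConfig(epochs=5))

    def test_config_ordering_enforced(self):
        with pytest.raises(ValueError):
            AEConfig(hidden1=50, hidden2=100)

    def test_untrained_transform_rejected(self):
        from gazeload.deep import StackedAutoencoder

        with pytest.raises(ValueError):
            StackedAutoencoder(AEConfig()).transform(np.zeros((2, 300)))


class TestPrepareRawWindows:
    def test_sixty_second_window_flattens_to_3600(self, default_study):
        data = prepare_raw_windows(
            default_study[:4], fs=30.0, window_s=60.0, flatten=True
        )
        assert data.X.shape == (4, 3600)

    def test_default_study_ae_matrix_shape(self, default_study):
        """The 360 one-minute segments flatten to a 360 x 3600 training
        matrix at 60 s windows, evenly split between the classes."""
        data = prepare_raw_windows(default_study, fs=30.0, window_s=60.0, flatten=True)
        assert data.X.shape == (360, 3600)
        assert (data.y == 0).sum() == (data.y == 1).sum() == 180

    def test_channeled_form(self, default_study):
        data = prepare_raw_windows(default_study[:4], fs=30.0, window_s=30.0)
        assert data.X.shape == (8, 900, 2)

    def test_decimation(self, default_study):
        data = prepare_raw_windows(
            default_study[:2], fs=30.0, window_s=30.0, target_len=120
        )
        assert data.X.shape == (4, 120, 2)

    def test_missing_samples_imputed(self, default_study):
        """Dropout — even at the segment ends — must not change the window
        count or introduce non-finite values."""
        import gazeload as gl
        from gazeload.trace import LabeledSegment

        seg = default_study[0]
        degraded = gl.degrade_trace(seg.trace, 0.0, 0.05, seed=1)
        degraded.valid[0] = degraded.valid[-1] = False
        degraded.x[0] = degraded.x[-1] = np.nan
        data = prepare_raw_windows(
            [LabeledSegment(degraded, seg.label, 0, 0)], fs=30.0, window_s=30.0
        )
        assert data.X.shape[0] == 2
        assert np.all(np.isfinite(data.X))


class TestAEHybrid:
    def test_learns_separable_toy(self):
        X, y = toy_dataset(n=120, S=64)
        flat = np.concatenate([X[:, :, 0], X[:, :, 1]], axis=1)
        preds = ae_svm_hybrid(flat, y, AEConfig(epochs=100, seed=0), CVScheme(k=3, seed=0))
        assert preds.accuracy >= 0.80
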