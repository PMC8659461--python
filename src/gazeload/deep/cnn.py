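"""16-layer 1-D convolutional network for raw gaze-window classification.

Layer census (16): one input layer; three blocks of convolution, batch
normalization, relu and max pooling (12); one fully connected layer; one
softmax layer; one classification output layer.  Features for the CNN+SVM
hybrid are the activations of the fully connected layer (layer 14).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..classifiers import CVScheme, PredictionSet, cross_validate_xy, cv_splits
from ._nn import Adam, BatchNorm1D, Conv1D, Dense, Flatten, MaxPool1D, ReLU, softmax

__all__ = ["CNNConfig", "CNN1D", "train_cnn", "extract_cnn_features", "cnn_svm_hybrid"]


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyperparameters.

    The layer census is fixed at 16; filter counts, kernel length, pooling
    length and the fully-connected width are configurable (they are not
    pinned by the architecture census).
    """

    filters: tuple[int, int, int] = (16, 32, 64)
    kernel: int = 7
    pool: int = 2
    fc_width: int = 64
    epochs: int = 30
    lr: float = 1e-3
    batch_size: int = 32
    seed: int = 0


LAYER_NAMES = (
    ["input"]
    + sum(
        [[f"conv{i}", f"batchnorm{i}", f"relu{i}", f"maxpool{i}"] for i in (1, 2, 3)],
        [],
    )
    + ["fully_connected", "softmax", "output"]
)


class CNN1D:
    """The network itself; ``fit``/``predict_proba``/``fc_features``."""

    def __init__(self, seq_len: int, channels: int, config: CNNConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        s = seq_len
        for _ in range(3):
            s //= config.pool
        if s < 1:
            raise ValueError("sequence shorter than the receptive field")
        f1, f2, f3 = config.filters
        self.blocks = []
        c_in = channels
        for f in (f1, f2, f3):
            self.blocks += [
                Conv1D(c_in, f, config.kernel, rng),
                BatchNorm1D(f),
                ReLU(),
                MaxPool1D(config.pool),
            ]
            c_in = f
        self.flatten = Flatten()
        self.fc = Dense(s * f3, config.fc_width, rng)
        self.fc_relu = ReLU()
        self.head = Dense(config.fc_width, 2, rng)  # linear part of the softmax layer
        self._layers = self.blocks + [self.flatten, self.fc, self.fc_relu, self.head]
        self.trained = False
        self.loss_history: list[float] = []

    @property
    def layer_names(self) -> list[str]:
        return list(LAYER_NAMES)

    @property
    def n_layers(self) -> int:
        return len(LAYER_NAMES)

    def _forward(self, X, train=True):
        h = X
        for layer in self.blocks:
            h = layer.forward(h, train)
        h = self.flatten.forward(h, train)
        fc_act = self.fc_relu.forward(self.fc.forward(h, train), train)
        logits = self.head.forward(fc_act, train)
        return logits, fc_act

    def _backward(self, grad):
        g = self.head.backward(grad)
        g = self.fc.backward(self.fc_relu.backward(g))
        g = self.flatten.backward(g)
        for layer in reversed(self.blocks):
            g = layer.backward(g)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CNN1D":
        from ._nn import softmax_cross_entropy

        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        opt = Adam(self._layers, lr=cfg.lr)
        n = len(X)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for b0 in range(0, n, cfg.batch_size):
                idx = order[b0 : b0 + cfg.batch_size]
                logits, _ = self._forward(X[idx], train=True)
                loss, grad = softmax_cross_entropy(logits, y[idx])
                self._backward(grad)
                opt.step()
                losses.append(loss)
            self.loss_history.append(float(np.mean(losses)))
        self.trained = True
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(X, train=False)
        return softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def fc_features(self, X: np.ndarray) -> np.ndarray:
        """Activations of the fully connected layer (layer 14)."""
        if not self.trained:
            raise ValueError("model is not trained")
        _, fc_act = self._forward(X, train=False)
        return fc_act


def train_cnn(
    X: np.ndarray, y: np.ndarray, config: CNNConfig, cv: CVScheme | None = None
) -> tuple[CNN1D, PredictionSet]:
    """K-fold out-of-fold CNN predictions plus a final model on all data.

    ``X`` is (N, S, 2).  Per-fold networks produce the out-of-fold
    predictions; the returned model is retrained on the full dataset for
    downstream feature extraction.
    """
    if X.ndim != 3:
        raise ValueError("CNN expects channeled windows (N, S, C)")
    if cv is None:
        cv = CVScheme(seed=config.seed)
    n = len(y)
    y_pred = np.full(n, -1)
    score = np.full(n, np.nan)
    fold_of = np.full(n, -1)
    for f, (tr, te) in enumerate(cv_splits(y, cv)):
        net = CNN1D(X.shape[1], X.shape[2], config).fit(X[tr], y[tr])
        proba = net.predict_proba(X[te])
        y_pred[te] = proba.argmax(axis=1)
        score[te] = proba[:, 1]
        fold_of[te] = f
    final = CNN1D(X.shape[1], X.shape[2], config).fit(X, y)
    seen = fold_of >= 0
    preds = PredictionSet(
        y[seen], y_pred[seen], score[seen], fold_of[seen], np.flatnonzero(seen)
    )
    return final, preds


def extract_cnn_features(model: CNN1D, X: np.ndarray) -> np.ndarray:
    """Per-window fully-connected-layer activation matrix (N, fc_width)."""
    return model.fc_features(X)


def cnn_svm_hybrid(
    model: CNN1D, X: np.ndarray, y: np.ndarray, cv: CVScheme | None = None
) -> PredictionSet:
    """CNN+SVM: linear SVM cross-validated on the CNN's FC-layer features."""
    from sklearn.svm import SVC

    if cv is None:
        cv = CVScheme(seed=model.config.seed)
    feats = extract_cnn_features(model, X)
    return cross_validate_xy(
        feats, y, lambda: SVC(kernel="linear", random_state=cv.seed), cv
    )
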