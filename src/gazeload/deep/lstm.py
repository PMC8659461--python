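"""5-layer LSTM classifier for raw gaze windows.

Layer census (5): sequence input; LSTM; fully connected; softmax;
classification output.  The LSTM propagates hidden state h_t and cell
state c_t over the S steps of a window; the last hidden state feeds the
fully connected layer.  Implemented in NumPy with full backpropagation
through time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..classifiers import CVScheme, PredictionSet, cv_splits
from ._nn import Adam, Dense, Layer, softmax, softmax_cross_entropy

__all__ = ["LSTMConfig", "LSTMClassifier", "train_lstm"]

LAYER_NAMES = ["sequence_input", "lstm", "fully_connected", "softmax", "output"]


@dataclass(frozen=True)
class LSTMConfig:
    hidden_units: int = 100
    epochs: int = 30
    lr: float = 1e-2
    batch_size: int = 32
    seed: int = 0


class _LSTMCell(Layer):
    """Single-layer LSTM over a whole batch of sequences; returns last h."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        scale = 1.0 / np.sqrt(hidden)
        self.params["Wx"] = rng.normal(0.0, scale, (c_in, 4 * hidden))
        self.params["Wh"] = rng.normal(0.0, scale, (hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.params["b"] = b
        self.hidden = hidden

    def forward(self, x, train=True):
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        N, S, _ = x.shape
        H = self.hidden
        h = np.zeros((N, H))
        c = np.zeros((N, H))
        self._cache = []
        self._x = x
        for t in range(S):
            z = x[:, t, :] @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        return h

    def backward(self, grad_h):
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        x = self._x
        N, S, C = x.shape
        H = self.hidden
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        db = np.zeros(4 * H)
        dx = np.zeros_like(x)
        dh = grad_h
        dc = np.zeros((N, H))
        for t in reversed(range(S)):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            dWx += x[:, t, :].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ Wx.T
            dh = dz @ Wh.T
            dc = dc * f
        self.grads["Wx"] = dWx
        self.grads["Wh"] = dWh
        self.grads["b"] = db
        return dx


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class LSTMClassifier:
    def __init__(self, channels: int, config: LSTMConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.cell = _LSTMCell(channels, config.hidden_units, rng)
        self.fc = Dense(config.hidden_units, 2, rng)
        self.trained = False
        self.loss_history: list[float] = []

    @property
    def layer_names(self) -> list[str]:
        return list(LAYER_NAMES)

    @property
    def n_layers(self) -> int:
        return len(LAYER_NAMES)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LSTMClassifier":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        opt = Adam([self.cell, self.fc], lr=cfg.lr)
        n = len(X)
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for b0 in range(0, n, cfg.batch_size):
                idx = order[b0 : b0 + cfg.batch_size]
                h = self.cell.forward(X[idx], train=True)
                logits = self.fc.forward(h, train=True)
                loss, grad = softmax_cross_entropy(logits, y[idx])
                self.cell.backward(self.fc.backward(grad))
                opt.step()
                losses.append(loss)
            self.loss_history.append(float(np.mean(losses)))
        self.trained = True
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        h = self.cell.forward(X, train=False)
        return softmax(self.fc.forward(h, train=False))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def train_lstm(
    X: np.ndarray, y: np.ndarray, config: LSTMConfig, cv: CVScheme | None = None
) -> tuple[LSTMClassifier, PredictionSet]:
    """K-fold out-of-fold LSTM predictions plus a final model on all data."""
    if X.ndim != 3:
        raise ValueError("LSTM expects channeled windows (N, S, C)")
    if cv is None:
        cv = CVScheme(seed=config.seed)
    n = len(y)
    y_pred = np.full(n, -1)
    score = np.full(n, np.nan)
    fold_of = np.full(n, -1)
    for f, (tr, te) in enumerate(cv_splits(y, cv)):
        net = LSTMClassifier(X.shape[2], config).fit(X[tr], y[tr])
        proba = net.predict_proba(X[te])
        y_pred[te] = proba.argmax(axis=1)
        score[te] = proba[:, 1]
        fold_of[te] = f
    final = LSTMClassifier(X.shape[2], config).fit(X, y)
    seen = fold_of >= 0
    preds = PredictionSet(
        y[seen], y_pred[seen], score[seen], fold_of[seen], np.flatnonzero(seen)
    )
    return final, preds
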