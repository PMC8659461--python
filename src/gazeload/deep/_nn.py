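"""Minimal NumPy neural-network layers with manual backprop.

Conventions: activations are (N, S, C) for sequence layers and (N, D) for
dense layers; conv layers use 'same' padding and stride 1; pooling is
non-overlapping.  Each layer stores its forward cache and exposes
``params``/``grads`` dicts consumed by :class:`Adam`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "BatchNorm1D",
    "ReLU",
    "MaxPool1D",
    "Flatten",
    "Dense",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray):
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(y)
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, grad / n


class Layer:
    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train=True):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution, 'same' padding, stride 1. x: (N, S, Cin) -> (N, S, F)."""

    def __init__(self, c_in: int, filters: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel length must be odd for 'same' padding")
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.params["W"] = rng.normal(0.0, scale, (kernel, c_in, filters))
        self.params["b"] = np.zeros(filters)
        self.kernel = kernel
        self.pad = kernel // 2

    def forward(self, x, train=True):
        W, b = self.params["W"], self.params["b"]
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        self._xp = xp
        N, S, _ = x.shape
        out = np.zeros((N, S, W.shape[2]))
        for k in range(self.kernel):
            out += xp[:, k : k + S, :] @ W[k]
        return out + b

    def backward(self, grad):
        W = self.params["W"]
        xp = self._xp
        N, S, F = grad.shape
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        for k in range(self.kernel):
            dW[k] = np.einsum("nsc,nsf->cf", xp[:, k : k + S, :], grad)
            dxp[:, k : k + S, :] += grad @ W[k].T
        self.grads["W"] = dW
        self.grads["b"] = grad.sum(axis=(0, 1))
        return dxp[:, self.pad : self.pad + S, :]


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (N, S). x: (N, S, C)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, grad):
        gamma = self.params["gamma"]
        xhat, std = self._xhat, self._std
        m = grad.shape[0] * grad.shape[1]
        self.grads["gamma"] = np.sum(grad * xhat, axis=(0, 1))
        self.grads["beta"] = np.sum(grad, axis=(0, 1))
        dxhat = grad * gamma
        return (
            dxhat - dxhat.mean(axis=(0, 1)) - xhat * np.mean(dxhat * xhat, axis=(0, 1))
        ) / std


class ReLU(Layer):
    def forward(self, x, train=True):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along S; trailing remainder is dropped."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x, train=True):
        N, S, C = x.shape
        S2 = S // self.pool
        xv = x[:, : S2 * self.pool, :].reshape(N, S2, self.pool, C)
        self._arg = xv.argmax(axis=2)
        self._in_shape = x.shape
        return xv.max(axis=2)

    def backward(self, grad):
        N, S2, C = grad.shape
        dx = np.zeros(self._in_shape)
        n_idx, s_idx, c_idx = np.meshgrid(
            np.arange(N), np.arange(S2), np.arange(C), indexing="ij"
        )
        dx[n_idx, s_idx * self.pool + self._arg, c_idx] = grad
        return dx


class Flatten(Layer):
    def forward(self, x, train=True):
        self._shape = x.shape
        return x.reshape(len(x), -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.params["W"] = rng.normal(0.0, scale, (d_in, d_out))
        self.params["b"] = np.zeros(d_out)

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class Adam:
    """Adaptive-moment optimizer over a list of layers."""

    def __init__(self, layers, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers
        ]

    def step(self):
        self.t += 1
        for i, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[i][k] = self.b1 * self.m[i][k] + (1 - self.b1) * g
                self.v[i][k] = self.b2 * self.v[i][k] + (1 - self.b2) * g * g
                mhat = self.m[i][k] / (1 - self.b1**self.t)
                vhat = self.v[i][k] / (1 - self.b2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
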