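"""Stacked autoencoder (100 -> 50 hidden units) plus SVM classification.

Two encoders are trained greedily: the first reconstructs the flattened
raw windows through a 100-unit bottleneck; the second reconstructs the
100-dimensional codes through a 50-unit bottleneck.  The 50-dimensional
codes feed an SVM.  Each stage is a single-hidden-layer MLP regression
(scikit-learn) whose hidden activations are the codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neural_network import MLPRegressor

from ..classifiers import CVScheme, PredictionSet, cross_validate_xy

__all__ = ["AEConfig", "StackedAutoencoder", "train_stacked_ae", "ae_svm_hybrid"]


@dataclass(frozen=True)
class AEConfig:
    hidden1: int = 100
    hidden2: int = 50
    epochs: int = 200  # max optimizer iterations per stage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden2 >= self.hidden1:
            raise ValueError("second encoder must be smaller than the first")


class _Stage:
    """One greedy autoencoder stage: X -> hidden -> X reconstruction."""

    def __init__(self, hidden: int, epochs: int, seed: int):
        self.mlp = MLPRegressor(
            hidden_layer_sizes=(hidden,),
            activation="relu",
            max_iter=epochs,
            random_state=seed,
            early_stopping=False,
        )

    def fit(self, X: np.ndarray) -> "_Stage":
        if self.mlp.hidden_layer_sizes[0] >= X.shape[1]:
            raise ValueError("hidden size must be smaller than the input dimension")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings at capped iters
            self.mlp.fit(X, X)
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        W, b = self.mlp.coefs_[0], self.mlp.intercepts_[0]
        return np.maximum(0.0, X @ W + b)

    @property
    def loss_curve(self) -> list[float]:
        return list(self.mlp.loss_curve_)


class StackedAutoencoder:
    def __init__(self, config: AEConfig):
        self.config = config
        self.stage1: _Stage | None = None
        self.stage2: _Stage | None = None

    def fit(self, X: np.ndarray) -> "StackedAutoencoder":
        cfg = self.config
        self.stage1 = _Stage(cfg.hidden1, cfg.epochs, cfg.seed).fit(X)
        codes1 = self.stage1.encode(X)
        self.stage2 = _Stage(cfg.hidden2, cfg.epochs, cfg.seed + 1).fit(codes1)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.stage1 is None or self.stage2 is None:
            raise ValueError("autoencoder is not trained")
        return self.stage2.encode(self.stage1.encode(X))

    @property
    def loss_curves(self) -> tuple[list[float], list[float]]:
        return self.stage1.loss_curve, self.stage2.loss_curve  # type: ignore[union-attr]


def train_stacked_ae(
    X: np.ndarray, config: AEConfig
) -> tuple[StackedAutoencoder, np.ndarray]:
    """Greedy two-stage training; returns the encoder stack and the
    (N, hidden2) reduced features."""
    if X.ndim != 2:
        raise ValueError("stacked AE expects flattened windows (N, D)")
    ae = StackedAutoencoder(config).fit(X)
    return ae, ae.transform(X)


def ae_svm_hybrid(
    X: np.ndarray,
    y: np.ndarray,
    config: AEConfig,
    cv: CVScheme | None = None,
    kernel: str = "rbf",
) -> PredictionSet:
    """AE+SVM: SVM cross-validated on the 50-dimensional codes.

    The default kernel is Gaussian: the codes are a learned nonlinear
    compression, where a linear margin is consistently weaker.
    """
    from sklearn.svm import SVC

    if cv is None:
        cv = CVScheme(seed=config.seed)
    _, feats = train_stacked_ae(X, config)
    return cross_validate_xy(
        feats, y, lambda: SVC(kernel=kernel, random_state=cv.seed), cv
    )
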