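"""Per-cell multilayer perceptron cancer score.

A regression MLP mapping one cell's feature vector to its cancer score:
three hidden layers of five times the input width (340 neurons for the
68-feature registry), each fully connected layer followed by batch
normalisation and ReLU, a single linear output neuron, MSE loss against the
binary region label, and the Adam optimiser at learning rate 1e-5 with
mini-batches of 128.  Training uses every 10th cell and a single epoch by
default — with millions of cells per slide that subsample is representative —
and both are configurable.  Classification applies a fixed threshold at the
midpoint of the label codes (0.5 for {0, 1}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, BatchNorm1d, Dense, ReLU, Sequential, mse_loss


@dataclass
class MLPConfig:
    hidden_multiplier: int = 5
    n_hidden_layers: int = 3
    learning_rate: float = 1e-5
    batch_size: int = 128
    epochs: int = 1
    subsample_stride: int = 10

    def hidden_width(self, n_features: int) -> int:
        return self.hidden_multiplier * n_features


@dataclass
class MLPModel:
    net: Sequential
    config: MLPConfig
    n_features: int
    label_midpoint: float

    def manifest(self) -> dict:
        return {
            "kind": "mlp",
            "n_features": self.n_features,
            "hidden_width": self.config.hidden_width(self.n_features),
            "n_hidden_layers": self.config.n_hidden_layers,
            "threshold": self.label_midpoint,
        }


def build_mlp(rng: np.random.Generator, n_features: int, config: MLPConfig) -> Sequential:
    width = config.hidden_width(n_features)
    layers = []
    n_in = n_features
    for _ in range(config.n_hidden_layers):
        layers += [Dense(rng, n_in, width), BatchNorm1d(width), ReLU()]
        n_in = width
    layers.append(Dense(rng, n_in, 1))
    return Sequential(*layers)


def train_mlp(
    X: np.ndarray,
    labels: np.ndarray,
    config: MLPConfig | None = None,
    seed: int = 0,
) -> MLPModel:
    """Train the regression MLP on per-cell features.

    ``labels`` must take exactly two distinct values; the classification
    threshold is fixed at their midpoint.  With a fixed seed training is
    deterministic.
    """
    config = config or MLPConfig()
    X = np.asarray(X, dtype=np.float32)
    y = np.asarray(labels, dtype=np.float32)
    codes = np.unique(y)
    if len(codes) != 2:
        raise ValueError(f"labels must take exactly two distinct values, got {codes}")
    midpoint = float(codes.mean())

    rng = np.random.default_rng(seed)
    net = build_mlp(rng, X.shape[1], config)
    opt = Adam(net.params, net.grads, lr=config.learning_rate)

    Xs = X[:: config.subsample_stride]
    ys = y[:: config.subsample_stride]
    n = len(Xs)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if len(idx) < 2:  # batch norm needs at least 2 samples
                continue
            pred = net.forward(Xs[idx], train=True)
            _, grad = mse_loss(pred, ys[idx, None])
            net.backward(grad.astype(np.float32))
            opt.step()
    return MLPModel(net, config, X.shape[1], midpoint)


def predict_mlp(model: MLPModel, X: np.ndarray, batch_size: int = 8192) -> np.ndarray:
    """Raw regression outputs (the cancer score before thresholding)."""
    X = np.asarray(X, dtype=np.float32)
    if X.shape[1] != model.n_features:
        raise ValueError("feature width differs from the trained model")
    outs = []
    for start in range(0, len(X), batch_size):
        outs.append(model.net.forward(X[start : start + batch_size], train=False)[:, 0])
    return np.concatenate(outs) if outs else np.zeros(0)
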