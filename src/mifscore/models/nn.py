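"""Minimal NumPy neural-network layers used by the MLP and U-net models.

Implements exactly the pieces those architectures need — dense and 2-D
convolution layers (im2col), batch normalisation, (Leaky)ReLU, nearest
up-sampling, an Adam optimiser and the MSE loss — with explicit forward and
backward passes.  Everything is float32, seeded through
``numpy.random.Generator``, and single-threaded deterministic.
"""

from __future__ import annotations

import numpy as np


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self):
        self.params, self.grads = [], []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Dense(Layer):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int):
        super().__init__()
        self.W = he_init(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        self.x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.grads[0][...] = self.x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class BatchNorm1d(Layer):
    """Batch normalisation over the batch axis with running statistics."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(n_features, dtype=np.float32)
        self.beta = np.zeros(n_features, dtype=np.float32)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self.inv_std = 1.0 / np.sqrt(var + self.eps)
        self.xhat = (x - mean) * self.inv_std
        return self.gamma * self.xhat + self.beta

    def backward(self, grad):
        n = grad.shape[0]
        self.grads[0][...] = (grad * self.xhat).sum(axis=0)
        self.grads[1][...] = grad.sum(axis=0)
        dxhat = grad * self.gamma
        return (
            self.inv_std
            / n
            * (n * dxhat - dxhat.sum(axis=0) - self.xhat * (dxhat * self.xhat).sum(axis=0))
        )


class ReLU(Layer):
    def __init__(self, slope: float = 0.0):
        super().__init__()
        self.slope = slope

    def forward(self, x, train=True):
        self.mask = x > 0
        return np.where(self.mask, x, self.slope * x)

    def backward(self, grad):
        return np.where(self.mask, grad, self.slope * grad)


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N, C, H, W) -> (N, C*kh*kw, Ho*Wo) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # (N, C, Ho, Wo, kh, kw)
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, ho * wo)
    return np.ascontiguousarray(cols), (ho, wo, x.shape)


class Conv2d(Layer):
    """2-D convolution via im2col; supports stride and zero padding."""

    def __init__(
        self,
        rng: np.random.Generator,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        pad: int | None = None,
    ):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        self.W = he_init(rng, (c_out, c_in, kernel, kernel), c_in * kernel * kernel)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train=True):
        self.x_shape = x.shape
        self.cols, (ho, wo, self.padded_shape) = _im2col(
            x.astype(np.float32), self.kernel, self.kernel, self.stride, self.pad
        )
        n = x.shape[0]
        c_out = self.W.shape[0]
        w_mat = self.W.reshape(c_out, -1)
        out = np.matmul(w_mat, self.cols) + self.b[None, :, None]
        self.out_hw = (ho, wo)
        return out.reshape(n, c_out, ho, wo)

    def backward(self, grad):
        n, c_out, ho, wo = grad.shape
        g = np.ascontiguousarray(grad.reshape(n, c_out, ho * wo))
        w_mat = self.W.reshape(c_out, -1)
        self.grads[0][...] = (
            np.matmul(g, self.cols.transpose(0, 2, 1)).sum(axis=0).reshape(self.W.shape)
        )
        self.grads[1][...] = g.sum(axis=(0, 2))
        dcols = np.matmul(w_mat.T, g)  # (N, C*kh*kw, L)
        # col2im: accumulate patches back onto the padded input
        _, c_in, hp, wp = self.padded_shape
        dx_pad = np.zeros((n, c_in, hp, wp), dtype=np.float32)
        dcols = dcols.reshape(n, c_in, self.kernel, self.kernel, ho, wo)
        s = self.stride
        for i in range(self.kernel):
            for j in range(self.kernel):
                dx_pad[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[:, :, i, j]
        if self.pad:
            dx_pad = dx_pad[:, :, self.pad : -self.pad or None, self.pad : -self.pad or None]
        return dx_pad[:, :, : self.x_shape[2], : self.x_shape[3]]


class UpsampleNearest(Layer):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x, train=True):
        f = self.factor
        return np.repeat(np.repeat(x, f, axis=2), f, axis=3)

    def backward(self, grad):
        f = self.factor
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // f, f, w // f, f).sum(axis=(3, 5))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)
        for layer in self.layers:
            self.params.extend(layer.params)
            self.grads.extend(layer.grads)

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adam optimiser over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params, grads, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean-squared error and its gradient w.r.t. the prediction."""
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff


def get_state(layer: Layer) -> list[np.ndarray]:
    """Copies of all parameters plus batch-norm running statistics."""
    state = [p.copy() for p in layer.params]
    for sub in _walk(layer):
        if isinstance(sub, BatchNorm1d):
            state.append(sub.running_mean.copy())
            state.append(sub.running_var.copy())
    return state


def set_state(layer: Layer, state: list[np.ndarray]) -> None:
    for p, s in zip(layer.params, state):
        p[...] = s
    i = len(layer.params)
    for sub in _walk(layer):
        if isinstance(sub, BatchNorm1d):
            sub.running_mean[...] = state[i]
            sub.running_var[...] = state[i + 1]
            i += 2


def _walk(layer: Layer):
    yield layer
    if isinstance(layer, Sequential):
        for sub in layer.layers:
            yield from _walk(sub)
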