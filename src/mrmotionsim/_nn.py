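"""Minimal NumPy neural-network layers with explicit backpropagation.

Just enough machinery for an encoder–decoder convolutional network: 2D
convolution (im2col), ReLU, batch normalization, 2x2 max pooling, stride-2
transposed convolution, channel concatenation, mean-squared-error loss and
the Adam optimizer. Arrays are NCHW float32. Every layer caches what its
backward pass needs; gradients are verified against numerical
differentiation in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """Same-padded k×k convolution (k odd), or 1×1 when k=1."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k = k
        self.pad = k // 2
        scale = np.sqrt(2.0 / (c_in * k * k))  # He initialization
        self.W = Param(rng.normal(0.0, scale, size=(c_out, c_in, k, k)))
        self.b = Param(np.zeros(c_out))
        self._cols = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        self._cols = cols
        self._xshape = x.shape
        y = np.einsum("nchwij,ocij->nohw", cols, self.W.value, optimize=True)
        return y + self.b.value[None, :, None, None]

    def backward(self, dy):
        cols = self._cols
        self.W.grad += np.einsum("nohw,nchwij->ocij", dy, cols, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dcols = np.einsum("nohw,ocij->nchwij", dy, self.W.value, optimize=True)
        n, c, h, w = self._xshape
        p = self.pad
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j]
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class BatchNorm2d(Layer):
    """Per-channel normalization over (N, H, W) with running statistics."""

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        self._cache = (xhat, invstd, training)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, dy):
        xhat, invstd, training = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        if not training:
            return dxhat * invstd[None, :, None, None]
        n, _, h, w = dy.shape
        m = n * h * w
        s1 = dxhat.sum(axis=(0, 2, 3))[None, :, None, None]
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return (invstd[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)


class MaxPool2(Layer):
    """2×2 max pooling with stride 2 (even input sides required)."""

    def forward(self, x, training):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"max pooling needs even spatial sides, got {h}x{w}")
        win = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(n, c, h // 2, w // 2, 4)
        self._arg = win.argmax(axis=-1)
        self._xshape = x.shape
        return win.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._xshape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=DTYPE)
        np.put_along_axis(flat, self._arg[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return flat.reshape(n, c, h, w)


class ConvTranspose2(Layer):
    """Stride-2 transposed convolution with a 2×2 kernel (doubles H and W)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.W = Param(rng.normal(0.0, scale, size=(c_in, c_out, 2, 2)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        n, c, h, w = x.shape
        y = np.einsum("nchw,coij->nohiwj", x, self.W.value, optimize=True)
        y = y.reshape(n, -1, 2 * h, 2 * w)
        return y + self.b.value[None, :, None, None]

    def backward(self, dy):
        x = self._x
        n, c, h, w = x.shape
        o = dy.shape[1]
        dyw = dy.reshape(n, o, h, 2, w, 2)
        self.W.grad += np.einsum("nchw,nohiwj->coij", x, dyw, optimize=True)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        return np.einsum("nohiwj,coij->nchw", dyw, self.W.value, optimize=True)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def concat_channels(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.concatenate([a, b], axis=1)


def split_channels(dy: np.ndarray, c_a: int) -> tuple[np.ndarray, np.ndarray]:
    return dy[:, :c_a], dy[:, c_a:]


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = (pred - target).astype(DTYPE)
    loss = float(np.mean(diff.astype(np.float64) ** 2))
    return loss, (2.0 / diff.size) * diff


class Adam:
    """Adam optimizer with bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float = 5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
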