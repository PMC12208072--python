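"""Minimal NumPy neural-network engine for 1D trace classification.

Implements exactly the layer vocabulary the classifier family needs — 1D
convolution (same padding), ReLU, non-overlapping max pooling, dropout,
dense layers, a sigmoid soft-attention mask and residual blocks with a
kernel-1 skip convolution — with manual backprop and an Adam optimizer.
Sized for desk-scale models: hundreds of traces, thousands of parameters,
CPU-only.  All randomness (init, dropout) flows from a single Generator.

Tensor convention: feature maps are ``(N, C, L)``; dense activations are
``(N, D)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from numpy.random import Generator


class ShapeError(ValueError):
    """A layer cannot process its input length (e.g. pooling mismatch)."""


class Layer:
    """Base layer: `params`/`grads` are parallel lists of arrays."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1D(Layer):
    """Same-padding 1D convolution (odd kernel), He-initialized."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError(f"kernel size must be odd, got {kernel}")
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, kernel
        fan_in = in_ch * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch, kernel))
        self.b = np.zeros(out_ch)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train: bool = False):
        N, C, L = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        win = sliding_window_view(xp, self.k, axis=2)  # (N, C, L, k) strided view
        self._win, self._in_shape = win, x.shape
        y = np.einsum("nclt,oct->nol", win, self.W, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, g):
        N, C, L = self._in_shape
        pad, k = self.k // 2, self.k
        self.grads[0][...] = np.einsum("nol,nclt->oct", g, self._win, optimize=True)
        self.grads[1][...] = g.sum(axis=(0, 2))
        dcols = np.einsum("nol,oct->nclt", g, self.W, optimize=True)
        dxp = np.zeros((N, C, L + 2 * pad))
        for t in range(k):
            dxp[:, :, t:t + L] += dcols[:, :, :, t]
        return dxp[:, :, pad:pad + L]


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: Generator):
        super().__init__()
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_dim), size=(out_dim, in_dim))
        self.b = np.zeros(out_dim)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, g):
        self.grads[0][...] = g.T @ self._x
        self.grads[1][...] = g.sum(axis=0)
        return g @ self.W


class ReLU(Layer):
    """Rectifier with a small leak so units cannot go permanently dead
    (tiny networks under heavy augmentation otherwise can collapse at
    init)."""

    def __init__(self, slope: float = 0.1):
        super().__init__()
        self.slope = slope

    def forward(self, x, train: bool = False):
        self._scale = np.where(x > 0, 1.0, self.slope)
        return x * self._scale

    def backward(self, g):
        return g * self._scale


class Sigmoid(Layer):
    def forward(self, x, train: bool = False):
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class MaxPool1D(Layer):
    """Non-overlapping max pooling; the window must divide the length."""

    def __init__(self, window: int, name: str = ""):
        super().__init__()
        self.window, self.name = window, name

    def forward(self, x, train: bool = False):
        N, C, L = x.shape
        S = self.window
        if L % S != 0:
            raise ShapeError(
                f"{self.name or 'max-pool'}: pooling window {S} does not divide length {L}")
        xr = x.reshape(N, C, L // S, S)
        self._arg = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, g):
        N, C, L = self._in_shape
        S = self.window
        dxr = np.zeros((N, C, L // S, S))
        np.put_along_axis(dxr, self._arg[..., None], g[..., None], axis=3)
        return dxr.reshape(N, C, L)


class Dropout(Layer):
    def __init__(self, p: float, rng: Generator):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p, self.rng = p, rng

    def forward(self, x, train: bool = False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class AttentionBlock(Layer):
    """Soft attention mask: a parallel conv branch squashed to [0, 1] per
    position, multiplied elementwise into the features."""

    def __init__(self, channels: int, kernel: int, rng: Generator):
        super().__init__()
        self.conv = Conv1D(channels, channels, kernel, rng)
        self.sig = Sigmoid()
        self.params = self.conv.params
        self.grads = self.conv.grads

    def forward(self, x, train: bool = False):
        self._x = x
        self._m = self.sig.forward(self.conv.forward(x, train), train)
        return x * self._m

    def backward(self, g):
        dx_direct = g * self._m
        dmask = self.sig.backward(g * self._x)
        return dx_direct + self.conv.backward(dmask)


class ResidualBlock(Layer):
    """Two same-padding convolutions with ReLUs, plus an optional skip path
    through a kernel-1 convolution, followed by max pooling and dropout.
    With the skip disabled the block is a plain convolutional block."""

    def __init__(self, in_ch: int, filters: int, kernel: int, pool: int,
                 dropout: float, skip: bool, rng: Generator, name: str = ""):
        super().__init__()
        self.conv1 = Conv1D(in_ch, filters, kernel, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv1D(filters, filters, kernel, rng)
        self.relu2 = ReLU()
        self.skip_conv = Conv1D(in_ch, filters, 1, rng) if skip else None
        self.pool = MaxPool1D(pool, name=name)
        self.drop = Dropout(dropout, rng)
        layers = [self.conv1, self.conv2] + ([self.skip_conv] if skip else [])
        self.params = [p for l in layers for p in l.params]
        self.grads = [gr for l in layers for gr in l.grads]

    def forward(self, x, train: bool = False):
        h = self.relu1.forward(self.conv1.forward(x, train), train)
        h = self.relu2.forward(self.conv2.forward(h, train), train)
        if self.skip_conv is not None:
            h = h + self.skip_conv.forward(x, train)
        return self.drop.forward(self.pool.forward(h, train), train)

    def backward(self, g):
        g = self.pool.backward(self.drop.backward(g))
        dx = self.conv1.backward(
            self.relu1.backward(self.conv2.backward(self.relu2.backward(g))))
        if self.skip_conv is not None:
            dx = dx + self.skip_conv.backward(g)
        return dx


class Adam:
    """Adam optimizer over a flat (params, grads) list pair."""

    def __init__(self, params, grads, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, y: np.ndarray):
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = len(y)
    loss = -np.log(np.clip(p[np.arange(n), y], 1e-12, None)).mean()
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return loss, g / n


def binary_cross_entropy_grad(logits: np.ndarray, y: np.ndarray):
    """Mean sigmoid BCE and its gradient w.r.t. the single-unit logits."""
    z = logits.ravel()
    p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    y = y.astype(float)
    loss = -(y * np.log(np.clip(p, 1e-12, None))
             + (1 - y) * np.log(np.clip(1 - p, 1e-12, None))).mean()
    g = ((p - y) / len(y)).reshape(logits.shape)
    return loss, g
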