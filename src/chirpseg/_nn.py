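"""Minimal numpy neural-network layers with manual backpropagation.

All layers operate on a single example shaped ``(channels, time)``.  Each
layer caches what its backward pass needs during ``forward(..., train=True)``,
so backward calls must mirror the forward order exactly (the U-Net driver in
:mod:`chirpseg.segmentation_model` guarantees this).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array plus its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Conv1d:
    """Same-padded 1-D convolution along the time axis.

    Frequency bins enter as input channels, so every first-level kernel mixes
    all frequency information at once.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        std = np.sqrt(2.0 / (in_ch * kernel))
        self.W = Param(rng.normal(0.0, std, size=(out_ch, in_ch * kernel)))
        self.b = Param(np.zeros(out_ch))
        self.k = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        self._cols = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad))) if pad else x
        # (C_in, T, k) -> (C_in * k, T)
        cols = sliding_window_view(xp, self.k, axis=1)
        cols = cols.transpose(0, 2, 1).reshape(self.in_ch * self.k, -1)
        if train:
            self._cols = cols
        return self.W.value @ cols + self.b.value[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols = self._cols
        self.W.grad += dy @ cols.T
        self.b.grad += dy.sum(axis=1)
        dcols = (self.W.value.T @ dy).reshape(self.in_ch, self.k, -1)
        T = dy.shape[1]
        pad = self.k // 2
        dxp = np.zeros((self.in_ch, T + 2 * pad))
        for j in range(self.k):
            dxp[:, j : j + T] += dcols[:, j, :]
        return dxp[:, pad : pad + T] if pad else dxp


class BatchNorm1d:
    """Per-channel normalization over the time axis with running statistics."""

    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(ch))
        self.beta = Param(np.zeros(ch))
        self.running_mean = np.zeros(ch)
        self.running_var = np.ones(ch)
        self.momentum = momentum
        self.eps = eps
        self._xhat = None
        self._std = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        shape = x.shape
        xf = x.reshape(shape[0], -1)  # normalize over all spatial axes
        if train:
            mu = xf.mean(axis=1)
            var = xf.var(axis=1)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            std = np.sqrt(var + self.eps)
            xhat = (xf - mu[:, None]) / std[:, None]
            self._xhat, self._std = xhat, std
        else:
            std = np.sqrt(self.running_var + self.eps)
            xhat = (xf - self.running_mean[:, None]) / std[:, None]
        y = self.gamma.value[:, None] * xhat + self.beta.value[:, None]
        return y.reshape(shape)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        shape = dy.shape
        dyf = dy.reshape(shape[0], -1)
        xhat, std = self._xhat, self._std
        self.gamma.grad += (dyf * xhat).sum(axis=1)
        self.beta.grad += dyf.sum(axis=1)
        dxhat = dyf * self.gamma.value[:, None]
        m1 = dxhat.mean(axis=1, keepdims=True)
        m2 = (dxhat * xhat).mean(axis=1, keepdims=True)
        return ((dxhat - m1 - xhat * m2) / std[:, None]).reshape(shape)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """Non-overlapping max pooling with window 2 (time length must be even)."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c, t = x.shape
        xr = x.reshape(c, t // 2, 2)
        if train:
            self._idx = xr.argmax(axis=2)
            self._shape = (c, t)
        return xr.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, t = self._shape
        dxr = np.zeros((c, t // 2, 2))
        np.put_along_axis(dxr, self._idx[:, :, None], dy[:, :, None], axis=2)
        return dxr.reshape(c, t)


class UpsampleNearest2:
    """Nearest-neighbour x2 upsampling along time."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(x, 2, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, t = dy.shape
        return dy.reshape(c, t // 2, 2).sum(axis=2)


class Conv2d:
    """Same-padded square 2-D convolution (used by the 2-D U-Net variant)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        std = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.W = Param(rng.normal(0.0, std, size=(out_ch, in_ch * kernel * kernel)))
        self.b = Param(np.zeros(out_ch))
        self.k = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        self._cols = None
        self._hw = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad))) if pad else x
        cols = sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        h, w = cols.shape[1], cols.shape[2]
        cols = cols.transpose(0, 3, 4, 1, 2).reshape(self.in_ch * self.k * self.k, h * w)
        if train:
            self._cols = cols
            self._hw = (h, w)
        else:
            self._hw = (h, w)
        y = self.W.value @ cols + self.b.value[:, None]
        return y.reshape(self.out_ch, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        h, w = self._hw
        dyf = dy.reshape(self.out_ch, h * w)
        self.W.grad += dyf @ self._cols.T
        self.b.grad += dyf.sum(axis=1)
        dcols = (self.W.value.T @ dyf).reshape(self.in_ch, self.k, self.k, h, w)
        pad = self.k // 2
        dxp = np.zeros((self.in_ch, h + 2 * pad, w + 2 * pad))
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w] += dcols[:, i, j]
        return dxp[:, pad : pad + h, pad : pad + w] if pad else dxp


class MaxPool2d2:
    """2x2 max pooling (both spatial dims must be even)."""

    def __init__(self):
        self._idx = None
        self._shape = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c, h, w = x.shape
        xr = (
            x.reshape(c, h // 2, 2, w // 2, 2)
            .transpose(0, 1, 3, 2, 4)
            .reshape(c, h // 2, w // 2, 4)
        )
        if train:
            self._idx = xr.argmax(axis=3)
            self._shape = (c, h, w)
        return xr.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = self._shape
        dxr = np.zeros((c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, self._idx[..., None], dy[..., None], axis=3)
        return (
            dxr.reshape(c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 3, 2, 4)
            .reshape(c, h, w)
        )


class UpsampleNearest2d2:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w = dy.shape
        return dy.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (p.grad - m)
            v += (1.0 - self.b2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
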