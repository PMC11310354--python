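"""Minimal NHWC neural-network layers with explicit backpropagation.

Everything here operates on float64 arrays of shape (N, H, W, C) — or
(N, F) after flattening — and is deterministic given the initialization
seed.  Each layer caches what its backward pass needs during
``forward(x, train=True)`` and returns the input gradient from
``backward(dout)``, accumulating parameter gradients in ``Param.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv3x3",
    "BatchNorm",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Flatten",
    "Linear",
    "Sequential",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 'same' convolution (zero padding), He-initialized."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (9 * c_in))
        # weights indexed (ky, kx, c_in, c_out)
        self.w = Param(rng.normal(0.0, std, size=(3, 3, c_in, c_out)))
        self.b = Param(np.zeros(c_out))
        self._xp: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        if train:
            self._xp = xp
        out = np.broadcast_to(self.b.value, (n, h, w, self.b.value.size)).copy()
        for di in range(3):
            for dj in range(3):
                out += xp[:, di:di + h, dj:dj + w, :] @ self.w.value[di, dj]
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xp = self._xp
        n, h, w, c_out = dout.shape
        dflat = dout.reshape(-1, c_out)
        dxp = np.zeros_like(xp)
        for di in range(3):
            for dj in range(3):
                patch = xp[:, di:di + h, dj:dj + w, :].reshape(-1, xp.shape[-1])
                self.w.grad[di, dj] += patch.T @ dflat
                dxp[:, di:di + h, dj:dj + w, :] += dout @ self.w.value[di, dj].T
        self.b.grad += dflat.sum(axis=0)
        return dxp[:, 1:-1, 1:-1, :]


class BatchNorm(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._xhat, self._inv_std, self._axes = xhat, inv_std, axes
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std, axes = self._xhat, self._inv_std, self._axes
        m = np.prod([dout.shape[a] for a in axes])
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value
        return (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).sum(axis=axes) / m
        ) * inv_std


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling; gradient is split evenly between tied maxima."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError("spatial sides must be even for 2x2 pooling")
        blocks = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = blocks.max(axis=(2, 4))
        if train:
            self._blocks, self._out = blocks, out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        blocks, out = self._blocks, self._out
        mask = blocks == out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        dblocks = mask * (dout[:, :, None, :, None, :] / counts)
        n, hh, _, ww, _, c = blocks.shape
        return dblocks.reshape(n, hh * 2, ww * 2, c)


class Upsample2(Layer):
    """Nearest-neighbor 2x upsampling."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, std, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout
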