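"""Forward/backward layer primitives operating on (batch, channels, length).

Every layer exposes ``forward(x, train)`` and ``backward(grad)``; learnable
layers carry :class:`Parameter` objects holding the value and its gradient.
The backward pass of each layer is verified against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Parameter", "Layer", "Conv1d", "BatchNorm1d", "ReLU", "MaxPool1d",
           "GlobalAvgPool", "Dropout", "Dense"]


class Parameter:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution (cross-correlation) with He-initialized weights."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int | None = None,
                 rng: np.random.Generator | None = None, bias: bool = True):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.padding = padding if padding is not None else kernel // 2
        fan_in = in_channels * kernel
        self.W = Parameter(rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                      size=(out_channels, in_channels, kernel)))
        self.b = Parameter(np.zeros(out_channels)) if bias else None
        self._cols: np.ndarray | None = None
        self._in_len = 0

    def parameters(self) -> list[Parameter]:
        return [self.W] + ([self.b] if self.b is not None else [])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._in_len = x.shape[2]
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        cols = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride]
        self._cols = cols  # (B, C, Lout, k)
        y = np.einsum("bclk,ock->bol", cols, self.W.value, optimize=True)
        if self.b is not None:
            y += self.b.value[None, :, None]
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols = self._cols
        self.W.grad += np.einsum("bol,bclk->ock", grad, cols, optimize=True)
        if self.b is not None:
            self.b.grad += grad.sum(axis=(0, 2))
        dcols = np.einsum("bol,ock->bclk", grad, self.W.value, optimize=True)
        B, C = cols.shape[0], cols.shape[1]
        p = self.padding
        lp = self._in_len + 2 * p
        dxp = np.zeros((B, C, lp))
        idx = np.arange(dcols.shape[2]) * self.stride
        for i in range(self.kernel):
            np.add.at(dxp, (slice(None), slice(None), idx + i), dcols[:, :, :, i])
        return dxp[:, :, p:lp - p] if p else dxp


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) / std[None, :, None]
        self._cache = (xhat, std, train)
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, std, train = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        g = grad * self.gamma.value[None, :, None]
        if not train:
            return g / std[None, :, None]
        m = grad.shape[0] * grad.shape[2]
        mean_g = g.mean(axis=(0, 2))[None, :, None]
        mean_gx = (g * xhat).mean(axis=(0, 2))[None, :, None]
        return (g - mean_g - xhat * mean_gx) / std[None, :, None]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool1d(Layer):
    def __init__(self, kernel: int = 3, stride: int = 2, padding: int = 1):
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        p = self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)), constant_values=-np.inf)
        windows = sliding_window_view(xp, self.kernel, axis=2)[:, :, ::self.stride]
        self._argmax = windows.argmax(axis=3)
        self._in_len = x.shape[2]
        return windows.max(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, Lout = grad.shape
        p = self.padding
        dxp = np.zeros((B, C, self._in_len + 2 * p))
        pos = np.arange(Lout) * self.stride + self._argmax  # (B, C, Lout)
        bidx = np.arange(B)[:, None, None]
        cidx = np.arange(C)[None, :, None]
        np.add.at(dxp, (bidx, cidx, pos), grad)
        return dxp[:, :, p:p + self._in_len] if p else dxp


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad[:, :, None], self._length, axis=2) / self._length


class Dropout(Layer):
    """Inverted dropout; draws its mask from the generator passed at init."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        self.rate = rate
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train and self.rate > 0:
            self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        else:
            self._mask = 1.0
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = Parameter(rng.normal(0.0, np.sqrt(2.0 / in_features),
                                      size=(out_features, in_features)))
        self.b = Parameter(np.zeros(out_features))

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W.value.T + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += grad.T @ self._x
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value
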