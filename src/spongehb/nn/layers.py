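"""Minimal CPU neural-network layers with explicit backpropagation.

Everything operates on float64 arrays in NCHW layout. Each layer exposes
``forward(x, train)`` and ``backward(grad_out)``; parameters are
:class:`Param` objects carrying their gradient, aggregated by the model
and updated by the optimizer in ``training.py``. Convolutions use
im2col/col2im so the heavy lifting is a single BLAS matmul.

Layer gradients are verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "GlobalAvgPool",
    "Dense",
    "sigmoid",
]


class Param:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _out_size(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """(N,C,H,W) -> (N*OH*OW, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    oh, ow = _out_size(h, k, stride, pad), _out_size(w, k, stride, pad)
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


def col2im(
    dcols: np.ndarray,
    x_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    pad: int,
    oh: int,
    ow: int,
) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add patches back to (N,C,H,W)."""
    n, c, h, w = x_shape
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float64)
    d6 = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d6[
                :, :, :, :, i, j
            ]
    if pad:
        dx = dx[:, :, pad:-pad, pad:-pad]
    return dx


class Conv2d(Layer):
    """2-D convolution, square kernel, He-normal init, optional bias."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        *,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_c, self.out_c, self.k = in_channels, out_channels, kernel_size
        self.stride = stride
        self.pad = pad if pad is not None else kernel_size // 2
        fan_in = in_channels * kernel_size * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Param(
            rng.standard_normal((out_channels, fan_in)) * scale, "conv.weight"
        )
        self.bias = Param(np.zeros(out_channels), "conv.bias") if bias else None
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        cols, oh, ow = im2col(x, self.k, self.stride, self.pad)
        out = cols @ self.weight.value.T
        if self.bias is not None:
            out += self.bias.value
        n = x.shape[0]
        self._cache = (x.shape, cols, oh, ow)
        return out.reshape(n, oh, ow, self.out_c).transpose(0, 3, 1, 2)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols, oh, ow = self._cache
        n = x_shape[0]
        g2 = grad.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_c)
        self.weight.grad += g2.T @ cols
        if self.bias is not None:
            self.bias.grad += g2.sum(axis=0)
        dcols = g2 @ self.weight.value
        return col2im(dcols, x_shape, self.k, self.stride, self.pad, oh, ow)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, train, x.shape)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, train, shape = self._cache
        n, c, h, w = shape
        m = n * h * w
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.value[None, :, None, None]
        if not train:
            return g * inv_std[None, :, None, None]
        sum_g = g.sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
        sum_gx = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
        return (
            inv_std[None, :, None, None]
            * (g - sum_g / m - xhat * sum_gx / m)
        )


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2d(Layer):
    """Max pooling; pads with -inf so padding never wins the max."""

    def __init__(self, kernel_size: int, stride: int, pad: int = 0) -> None:
        self.k, self.stride, self.pad = kernel_size, stride, pad
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        oh, ow = _out_size(h, k, s, p), _out_size(w, k, s, p)
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(n, c, oh, ow, k * k)
        idx = flat.argmax(axis=-1)
        self._cache = (x.shape, idx, oh, ow)
        return np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, idx, oh, ow = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        dflat = np.zeros((n, c, oh, ow, k * k), dtype=np.float64)
        np.put_along_axis(dflat, idx[..., None], grad[..., None], axis=-1)
        # scatter back with the conv adjoint (channel-wise: C patches of size k*k)
        dcols = dflat.transpose(0, 2, 3, 1, 4).reshape(n * oh * ow, c * k * k)
        return col2im(dcols, x_shape, k, s, p, oh, ow)


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean (the squeeze step of SE blocks)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], self._shape) / (h * w)


class Dense(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        *,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng if rng is not None else np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.weight = Param(rng.standard_normal((in_features, out_features)) * scale, "dense.weight")
        self.bias = Param(np.zeros(out_features), "dense.bias") if bias else None
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        out = x @ self.weight.value
        if self.bias is not None:
            out += self.bias.value
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += self._x.T @ grad
        if self.bias is not None:
            self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T
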