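"""Differentiable layers on NCHW float32 arrays.

Each layer exposes ``forward(x, train=False)`` and ``backward(grad)``;
``backward`` may only be called after a ``forward(..., train=True)`` that
cached the needed intermediates.  Multi-input layers (``Add``, ``Concat``)
take a list of arrays and return a list of gradients.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A learnable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x, train: bool = False):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    """(N,C,H,W) -> column matrix (N, oh*ow, C*kh*kw)."""
    n = x.shape[0]
    win = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    _, c, oh, ow = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def _col2im(
    dcols: np.ndarray,
    x_shape: tuple[int, int, int, int],
    kh: int,
    kw: int,
    stride: int,
    oh: int,
    ow: int,
) -> np.ndarray:
    """Scatter-add of column gradients back to the (padded) input."""
    n, c, h, w = x_shape
    dx = np.zeros((n, c, h, w), dtype=dcols.dtype)
    d = dcols.reshape(n, oh, ow, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d[
                :, :, :, :, i, j
            ]
    return dx


class Conv2d(Layer):
    """2-D convolution (cross-correlation), He-normal initialized."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        bias: bool = False,
        rng: np.random.Generator | None = None,
        name: str = "",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel, kernel))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_channels), f"{name}.bias") if bias else None
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.in_channels, self.out_channels = in_channels, out_channels
        self._cache = None

    def params(self) -> list[Param]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.pad:
            x = np.pad(
                x, ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad))
            )
        cols, oh, ow = _im2col(x, self.kernel, self.kernel, self.stride)
        wmat = self.weight.value.reshape(self.out_channels, -1)
        out = cols @ wmat.T
        if self.bias is not None:
            out += self.bias.value
        out = out.transpose(0, 2, 1).reshape(-1, self.out_channels, oh, ow)
        if train:
            self._cache = (cols, x.shape, oh, ow)
        else:
            self._cache = None
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape, oh, ow = self._cache
        n = grad.shape[0]
        d = grad.reshape(n, self.out_channels, oh * ow).transpose(0, 2, 1)
        wmat = self.weight.value.reshape(self.out_channels, -1)
        dw = np.einsum("nlo,nlk->ok", d, cols)
        self.weight.grad += dw.reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += d.sum(axis=(0, 1))
        dcols = d @ wmat
        dx = _col2im(dcols, x_shape, self.kernel, self.kernel, self.stride, oh, ow)
        if self.pad:
            dx = dx[:, :, self.pad : -self.pad or None, self.pad : -self.pad or None]
        return dx


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, name: str = "") -> None:
        self.gamma = Param(np.ones(channels), f"{name}.gamma")
        self.beta = Param(np.zeros(channels), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        g = self.gamma.value[None, :, None, None]
        b = self.beta.value[None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(np.float32)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(np.float32)
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
            self._cache = (xhat, inv)
            return (g * xhat + b).astype(np.float32)
        inv = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * inv[None, :, None, None]
        return (g * xhat + b).astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        g = self.gamma.value[None, :, None, None]
        m = grad.shape[0] * grad.shape[2] * grad.shape[3]
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        dxhat = grad * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv[None, :, None, None]
        return dx.astype(np.float32)


class ReLU(Layer):
    def __init__(self) -> None:
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2d(Layer):
    """Max pooling; ``stride`` defaults to ``kernel`` (non-overlapping)."""

    def __init__(self, kernel: int, stride: int | None = None, pad: int = 0) -> None:
        self.kernel = kernel
        self.stride = stride if stride is not None else kernel
        self.pad = pad
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if self.pad:
            x = np.pad(
                x,
                ((0, 0), (0, 0), (self.pad, self.pad), (self.pad, self.pad)),
                constant_values=-np.inf,
            )
        k, s = self.kernel, self.stride
        win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        n, c, oh, ow = win.shape[:4]
        flat = win.reshape(n, c, oh, ow, k * k)
        out = flat.max(axis=-1)
        if train:
            self._cache = (flat.argmax(axis=-1), x.shape, oh, ow)
        return out.astype(np.float32)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        argmax, x_shape, oh, ow = self._cache
        k, s = self.kernel, self.stride
        dx = np.zeros(x_shape, dtype=grad.dtype)
        for i in range(k):
            for j in range(k):
                mask = argmax == (i * k + j)
                dx[:, :, i : i + s * oh : s, j : j + s * ow : s] += grad * mask
        if self.pad:
            dx = dx[:, :, self.pad : -self.pad or None, self.pad : -self.pad or None]
        return dx


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def __init__(self) -> None:
        self._shape = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(grad[:, :, None, None], (n, c, h, w)) / (h * w)


class GlobalMaxPool(Layer):
    """(N,C,H,W) -> (N,C) spatial max."""

    def __init__(self) -> None:
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x.max(axis=(2, 3))
        if train:
            self._cache = (x == out[:, :, None, None], x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        mask, shape = self._cache
        counts = mask.sum(axis=(2, 3), keepdims=True)
        return mask * grad[:, :, None, None] / counts


class Linear(Layer):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
        name: str = "",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), (out_features, in_features))
        self.weight = Param(w, f"{name}.weight")
        self.bias = Param(np.zeros(out_features), f"{name}.bias")
        self._x = None

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value


class Add(Layer):
    """Elementwise sum of two (or more) same-shaped inputs."""

    def __init__(self) -> None:
        self._n = 2

    def forward(self, xs: Sequence[np.ndarray], train: bool = False) -> np.ndarray:
        self._n = len(xs)
        out = xs[0].copy()
        for x in xs[1:]:
            out += x
        return out

    def backward(self, grad: np.ndarray) -> list[np.ndarray]:
        return [grad] * self._n


class Concat(Layer):
    """Channel concatenation of feature vectors.

    4-D inputs are flattened to (N, C*H*W) first, so pooled maps of
    spatial size 1 x 1 concatenate naturally with (N, C) vectors.
    """

    def __init__(self) -> None:
        self._shapes = None

    def forward(self, xs: Sequence[np.ndarray], train: bool = False) -> np.ndarray:
        flats = [x.reshape(x.shape[0], -1) for x in xs]
        if train:
            self._shapes = [x.shape for x in xs]
        return np.concatenate(flats, axis=1)

    def backward(self, grad: np.ndarray) -> list[np.ndarray]:
        out, at = [], 0
        for shape in self._shapes:
            size = int(np.prod(shape[1:]))
            out.append(grad[:, at : at + size].reshape(shape))
            at += size
        return out
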