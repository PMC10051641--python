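"""Layers with forward/backward passes.

Every layer exposes ``forward(x, train=False)``, ``backward(grad)`` and
``params()`` (list of :class:`Param`).  ``backward`` must be called with the
gradient of the loss w.r.t. the last ``forward`` output and returns the
gradient w.r.t. that forward's input.  Layers cache whatever the backward
pass needs; they are therefore not reentrant across interleaved forwards.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name

    @property
    def size(self) -> int:
        return int(self.value.size)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N,C,H,W) -> (N*H'*W', C*k*k) patch matrix for stride-1 convolution."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # windows: (N, C, H', W', k, k)
    win = sliding_window_view(x, (k, k), axis=(2, 3))
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
    return np.ascontiguousarray(cols, dtype=DTYPE)


class Layer:
    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError

    def params(self):
        return []


class Conv2D(Layer):
    """Stride-1 2-D cross-correlation with 'same' padding (or 'valid' for k=1).

    Weight shape (C_out, C_in, k, k); parameter count (k*k*C_in + 1) * C_out.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, *, rng: np.random.Generator, name: str = ""):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = k // 2
        fan_in = c_in * k * k
        fan_out = c_out * k * k
        self.W = Param(glorot_uniform(rng, (c_out, c_in, k, k), fan_in, fan_out), name + ".W")
        self.b = Param(np.zeros(c_out), name + ".b")
        self._cols = None
        self._in_shape = None

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        cols = _im2col(x, self.k, self.pad)
        self._cols = cols if train else None
        self._in_shape = x.shape
        wmat = self.W.value.reshape(self.c_out, -1)
        out = cols @ wmat.T + self.b.value
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, _, h, w = self._in_shape
        g = np.ascontiguousarray(grad.transpose(0, 2, 3, 1), dtype=DTYPE).reshape(-1, self.c_out)
        self.b.grad += g.sum(axis=0)
        self.W.grad += (g.T @ self._cols).reshape(self.W.value.shape)
        # dx = correlation of grad with the 180deg-rotated, channel-swapped kernel
        w_flip = self.W.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (C_in, C_out, k, k)
        cols_g = _im2col(grad.astype(DTYPE, copy=False), self.k, self.pad)
        dx = cols_g @ w_flip.reshape(self.c_in, -1).T
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)

    def params(self):
        return [self.W, self.b]


class Upsample2x(Layer):
    """Zero-insertion 2x upsampling; followed by a Conv2D it realises a
    stride-2 transposed convolution."""

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        out = np.zeros((n, c, 2 * h, 2 * w), dtype=DTYPE)
        out[:, :, ::2, ::2] = x
        return out

    def backward(self, grad):
        return np.ascontiguousarray(grad[:, :, ::2, ::2], dtype=DTYPE)


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2.  Ties share the gradient equally."""

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("MaxPool2D requires even spatial dims")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            mask = xr == out[:, :, :, None, :, None]
            self._mask = mask
            self._count = mask.sum(axis=(3, 5), keepdims=True)
            self._shape = x.shape
        return out

    def backward(self, grad):
        n, c, h, w = self._shape
        g = grad[:, :, :, None, :, None] / self._count
        return (g * self._mask).reshape(n, c, h, w).astype(DTYPE, copy=False)


class AvgPool2D(Layer):
    """2x2 average pooling, stride 2."""

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("AvgPool2D requires even spatial dims")
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, grad):
        n, c, h, w = self._shape
        g = np.broadcast_to(grad[:, :, :, None, :, None] / 4.0, (n, c, h // 2, 2, w // 2, 2))
        return g.reshape(n, c, h, w).astype(DTYPE, copy=False)


class _BatchNormBase(Layer):
    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5, name: str = ""):
        self.gamma = Param(np.ones(n_features), name + ".gamma")
        self.beta = Param(np.zeros(n_features), name + ".beta")
        self.running_mean = np.zeros(n_features, dtype=DTYPE)
        self.running_var = np.ones(n_features, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    _axes: tuple = ()

    def _reshape(self, v):
        raise NotImplementedError

    def forward(self, x, train: bool = False):
        if train:
            mean = x.mean(axis=self._axes)
            var = x.var(axis=self._axes)
            self.running_mean = (self.momentum * self.running_mean + (1 - self.momentum) * mean).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var + (1 - self.momentum) * var).astype(DTYPE)
            self._std = np.sqrt(var + self.eps)
            self._xhat = (x - self._reshape(mean)) / self._reshape(self._std)
            self._m = x.size // mean.size
            return self._reshape(self.gamma.value) * self._xhat + self._reshape(self.beta.value)
        std = np.sqrt(self.running_var + self.eps)
        xhat = (x - self._reshape(self.running_mean)) / self._reshape(std)
        return self._reshape(self.gamma.value) * xhat + self._reshape(self.beta.value)

    def backward(self, grad):
        xhat, std, m = self._xhat, self._std, self._m
        dg = (grad * xhat).sum(axis=self._axes)
        db = grad.sum(axis=self._axes)
        self.gamma.grad += dg
        self.beta.grad += db
        dxhat = grad * self._reshape(self.gamma.value)
        dx = (dxhat - self._reshape(dxhat.sum(axis=self._axes) / m)
              - xhat * self._reshape((dxhat * xhat).sum(axis=self._axes) / m)) / self._reshape(std)
        return dx.astype(DTYPE, copy=False)

    def params(self):
        return [self.gamma, self.beta]


class BatchNorm2D(_BatchNormBase):
    """Per-channel batch normalisation over (N, H, W)."""

    _axes = (0, 2, 3)

    def _reshape(self, v):
        return v.reshape(1, -1, 1, 1)


class BatchNorm1D(_BatchNormBase):
    """Per-feature batch normalisation over the batch axis."""

    _axes = (0,)

    def _reshape(self, v):
        return v.reshape(1, -1)


class Dropout(Layer):
    """Inverted dropout; identity at inference.  Draws from the rng handed in
    at construction so whole-model runs are reproducible from one seed."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train: bool = False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, *, rng: np.random.Generator, name: str = ""):
        self.d_in, self.d_out = d_in, d_out
        self.W = Param(glorot_uniform(rng, (d_in, d_out), d_in, d_out), name + ".W")
        self.b = Param(np.zeros(d_out), name + ".b")

    def forward(self, x, train: bool = False):
        self._x = x if train else None
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return (grad @ self.W.value.T).astype(DTYPE, copy=False)

    def params(self):
        return [self.W, self.b]


class Flatten(Layer):
    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class ReLU(Layer):
    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Sigmoid(Layer):
    # logits are clipped to +-15: beyond that the output is saturated anyway
    # (sigmoid(15) = 1 - 3e-7) and a tighter clip keeps the gradient
    # out*(1-out) representable in float32, so optimisers can recover from
    # saturation instead of dying on underflowed squared gradients
    def forward(self, x, train: bool = False):
        out = 1.0 / (1.0 + np.exp(-np.clip(x, -15, 15)))
        self._out = out
        return out.astype(DTYPE, copy=False)

    def backward(self, grad):
        return grad * self._out * (1.0 - self._out)


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x, train: bool = False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_params(self) -> int:
        return sum(p.size for p in self.params())
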