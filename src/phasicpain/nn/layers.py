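"""Layer implementations with explicit forward/backward passes.

Tensors are NCHW (batch, channels, height, width) for spatial layers and
(batch, features) for dense layers.  Each layer exposes ``params`` — a list
of ``Param`` objects holding the value and its accumulated gradient — and
``forward(x, train)`` / ``backward(dout)`` methods; ``backward`` must be
called after the matching ``forward`` (layers cache what they need).
"""

from __future__ import annotations

import numpy as np

#: Engine dtype; float32 keeps desk-scale training fast on one CPU.
DTYPE = np.float32


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    """Base class: parameter-free identity."""

    params: list[Param]

    def __init__(self):
        self.params = []

    def initialize(self, rng: np.random.Generator) -> None:  # noqa: ARG002
        pass

    def forward(self, x, train=False):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError


def _im2col(x, kh, kw, stride, pad):
    """(N,C,H,W) -> (N, C, kh*kw, out_h*out_w) patch matrix."""
    n, c, h, w = x.shape
    out_h = (h + 2 * pad - kh) // stride + 1
    out_w = (w + 2 * pad - kw) // stride + 1
    if out_h < 1 or out_w < 1:
        raise ValueError(f"kernel {kh}x{kw} does not fit input {h}x{w}")
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    cols = np.empty((n, c, kh, kw, out_h, out_w), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i:i + stride * out_h:stride,
                                  j:j + stride * out_w:stride]
    return cols.reshape(n, c, kh * kw, out_h * out_w), out_h, out_w


def _col2im(dcols, x_shape, kh, kw, stride, pad):
    """Adjoint of :func:`_im2col`: scatter-add patches back to the image."""
    n, c, h, w = x_shape
    out_h = (h + 2 * pad - kh) // stride + 1
    out_w = (w + 2 * pad - kw) // stride + 1
    dcols = dcols.reshape(n, c, kh, kw, out_h, out_w)
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i:i + stride * out_h:stride,
                j:j + stride * out_w:stride] += dcols[:, :, i, j]
    return dxp[:, :, pad:pad + h, pad:pad + w] if pad else dxp


class Conv2D(Layer):
    """2-D convolution (cross-correlation), same-style zero padding."""

    def __init__(self, in_channels, out_channels, kernel=3, stride=1, pad=1,
                 bias=True):
        super().__init__()
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.stride, self.pad = stride, pad
        self.w = Param(np.zeros((out_channels, in_channels, kernel, kernel), dtype=DTYPE))
        self.params = [self.w]
        self.b = None
        if bias:
            self.b = Param(np.zeros(out_channels, dtype=DTYPE))
            self.params.append(self.b)

    def initialize(self, rng):
        fan_in = self.cin * self.k * self.k
        self.w.value = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), self.w.value.shape
        ).astype(self.w.value.dtype)

    def forward(self, x, train=False):
        cols, out_h, out_w = _im2col(x, self.k, self.k, self.stride, self.pad)
        colsf = cols.reshape(x.shape[0], -1, cols.shape[-1])
        self._cache = (x.shape, colsf, cols.shape)
        wmat = self.w.value.reshape(self.cout, -1)
        out = np.matmul(wmat, colsf)  # (n, cout, L) via stacked BLAS
        if self.b is not None:
            out += self.b.value[None, :, None]
        return out.reshape(x.shape[0], self.cout, out_h, out_w)

    def backward(self, dout):
        x_shape, colsf, cols_shape = self._cache
        n = x_shape[0]
        dout2 = dout.reshape(n, self.cout, -1)
        self.w.grad += np.tensordot(
            dout2, colsf, axes=([0, 2], [0, 2])
        ).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += dout2.sum(axis=(0, 2))
        wmat = self.w.value.reshape(self.cout, -1)
        dcols = np.matmul(wmat.T, dout2)
        return _col2im(dcols.reshape(cols_shape), x_shape, self.k, self.k,
                       self.stride, self.pad)


class DepthwiseConv2D(Layer):
    """Per-channel 2-D convolution (channel multiplier 1)."""

    def __init__(self, channels, kernel=3, stride=1, pad=1):
        super().__init__()
        self.c, self.k, self.stride, self.pad = channels, kernel, stride, pad
        self.w = Param(np.zeros((channels, kernel, kernel), dtype=DTYPE))
        self.b = Param(np.zeros(channels, dtype=DTYPE))
        self.params = [self.w, self.b]

    def initialize(self, rng):
        fan_in = self.k * self.k
        self.w.value = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), self.w.value.shape
        ).astype(self.w.value.dtype)

    def forward(self, x, train=False):
        cols, out_h, out_w = _im2col(x, self.k, self.k, self.stride, self.pad)
        self._cache = (x.shape, cols)
        wflat = self.w.value.reshape(self.c, -1)
        out = np.einsum("ck,nckl->ncl", wflat, cols) + self.b.value[None, :, None]
        return out.reshape(x.shape[0], self.c, out_h, out_w)

    def backward(self, dout):
        x_shape, cols = self._cache
        dout2 = dout.reshape(x_shape[0], self.c, -1)
        self.w.grad += np.einsum("ncl,nckl->ck", dout2, cols).reshape(self.w.value.shape)
        self.b.grad += dout2.sum(axis=(0, 2))
        wflat = self.w.value.reshape(self.c, -1)
        dcols = np.einsum("ck,ncl->nckl", wflat, dout2)
        return _col2im(dcols, x_shape, self.k, self.k, self.stride, self.pad)


class BatchNorm2D(Layer):
    """Batch normalization over (N, H, W) per channel, with running stats."""

    def __init__(self, channels, momentum=0.9, eps=1e-5):
        super().__init__()
        self.gamma = Param(np.ones(channels, dtype=DTYPE))
        self.beta = Param(np.zeros(channels, dtype=DTYPE))
        self.params = [self.gamma, self.beta]
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std, x.shape, train)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, dout):
        xhat, inv_std, x_shape, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not train:
            return dout * g * inv_std[None, :, None, None]
        dxhat = dout * g
        term = dxhat - dxhat.mean(axis=(0, 2, 3), keepdims=True) \
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return term * inv_std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class ReLU6(Layer):
    def forward(self, x, train=False):
        self._mask = (x > 0) & (x < 6.0)
        return np.clip(x, 0.0, 6.0)

    def backward(self, dout):
        return dout * self._mask


class MaxPool2D(Layer):
    def __init__(self, kernel=3, stride=2):
        super().__init__()
        self.k, self.stride = kernel, stride

    def forward(self, x, train=False):
        cols, out_h, out_w = _im2col(x, self.k, self.k, self.stride, 0)
        self._argmax = cols.argmax(axis=2)
        self._cache = (x.shape, cols.shape)
        out = cols.max(axis=2)
        return out.reshape(x.shape[0], x.shape[1], out_h, out_w)

    def backward(self, dout):
        x_shape, cols_shape = self._cache
        dcols = np.zeros(cols_shape, dtype=dout.dtype)
        n, c, kk, ll = cols_shape
        flat = dout.reshape(n, c, ll)
        ni, ci, li = np.ogrid[:n, :c, :ll]
        dcols[ni, ci, self._argmax, li] = flat
        return _col2im(dcols, x_shape, self.k, self.k, self.stride, 0)


class GlobalAvgPool(Layer):
    """(N,C,H,W) -> (N,C) spatial mean."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features, out_features):
        super().__init__()
        self.din, self.dout_ = in_features, out_features
        self.w = Param(np.zeros((in_features, out_features), dtype=DTYPE))
        self.b = Param(np.zeros(out_features, dtype=DTYPE))
        self.params = [self.w, self.b]

    def initialize(self, rng):
        self.w.value = rng.normal(
            0.0, np.sqrt(2.0 / self.din), self.w.value.shape
        ).astype(self.w.value.dtype)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T
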