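"""Minimal NumPy neural-network primitives with manual backpropagation.

Implements exactly what the pix2pix-style translator needs: strided 4x4
convolutions, transposed convolutions, instance normalization, leaky-ReLU /
ReLU / tanh activations, binary cross-entropy with logits, L1, and Adam.
Tensors are NCHW float32.  Every layer caches its forward inputs and exposes
``backward(dy) -> dx`` that also accumulates parameter gradients; gradients
are verified against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

F32 = np.float32


class Param:
    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)


class Adam:
    def __init__(self, params: list[Param], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p in self.params:
            p.m[...] = b1 * p.m + (1 - b1) * p.grad
            p.v[...] = b2 * p.v + (1 - b2) * p.grad**2
            p.value -= self.lr * (p.m / bias1) / (np.sqrt(p.v / bias2) + self.eps)


# ---------------------------------------------------------------------------
# im2col / col2im

def im2col(x: np.ndarray, k: int, stride: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    _, _, oh, ow, _, _ = win.shape
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, oh * ow, c * k * k)
    return np.ascontiguousarray(cols), oh, ow


def col2im(cols: np.ndarray, out_shape: tuple[int, int, int, int],
           k: int, stride: int, pad: int, oh: int, ow: int) -> np.ndarray:
    """Scatter-add columns back onto the (padded) image grid; adjoint of im2col."""
    n, c, h, w = out_shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols6 = cols.reshape(n, oh, ow, c, k, k)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += \
                cols6[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    if pad == 0:
        return xp
    return xp[:, :, pad:pad + h, pad:pad + w]


# ---------------------------------------------------------------------------
# layers

class Layer:
    params: list[Param] = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    __call__ = lambda self, x: self.forward(x)


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 4, stride: int = 2, pad: int = 1, init_sd: float = 0.02):
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(rng.normal(0.0, init_sd, (c_in * k * k, c_out)))
        self.b = Param(np.zeros(c_out))
        self.params = [self.W, self.b]

    def forward(self, x):
        self._x_shape = x.shape
        self._cols, self._oh, self._ow = im2col(x, self.k, self.stride, self.pad)
        y = self._cols @ self.W.value + self.b.value
        n = x.shape[0]
        return y.reshape(n, self._oh, self._ow, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dy):
        n = dy.shape[0]
        dyf = dy.transpose(0, 2, 3, 1).reshape(n, -1, self.c_out)
        self.W.grad += np.tensordot(self._cols, dyf, axes=([0, 1], [0, 1]))
        self.b.grad += dyf.sum(axis=(0, 1))
        dcols = dyf @ self.W.value.T
        return col2im(dcols, self._x_shape, self.k, self.stride, self.pad,
                      self._oh, self._ow)


class ConvTranspose2d(Layer):
    """Fractionally-strided convolution; exact adjoint of Conv2d geometry."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 k: int = 4, stride: int = 2, pad: int = 1, init_sd: float = 0.02):
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.W = Param(rng.normal(0.0, init_sd, (c_in, c_out * k * k)))
        self.b = Param(np.zeros(c_out))
        self.params = [self.W, self.b]

    def out_size(self, s: int) -> int:
        return (s - 1) * self.stride - 2 * self.pad + self.k

    def forward(self, x):
        n, c, h, w = x.shape
        self._in_hw = (h, w)
        self._xf = x.transpose(0, 2, 3, 1).reshape(n, h * w, c)
        cols = self._xf @ self.W.value
        ho, wo = self.out_size(h), self.out_size(w)
        y = col2im(cols, (n, self.c_out, ho, wo), self.k, self.stride, self.pad, h, w)
        return y + self.b.value[None, :, None, None]

    def backward(self, dy):
        n = dy.shape[0]
        h, w = self._in_hw
        dcols, oh, ow = im2col(dy, self.k, self.stride, self.pad)
        assert (oh, ow) == (h, w)
        self.W.grad += np.tensordot(self._xf, dcols, axes=([0, 1], [0, 1]))
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dxf = dcols @ self.W.value.T
        return dxf.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, c: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.params = [self.gamma, self.beta]

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        self._inv_sd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_sd
        return self.gamma.value[None, :, None, None] * self._xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, dy):
        self.gamma.grad += (dy * self._xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.value[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * self._xhat).mean(axis=(2, 3), keepdims=True)
        return self._inv_sd * (dxhat - m1 - self._xhat * m2)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        self._scale = np.where(x > 0, F32(1.0), F32(self.slope))
        return x * self._scale

    def backward(self, dy):
        return dy * self._scale


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return dy * (1.0 - self._y**2)


# ---------------------------------------------------------------------------
# losses (mean-reduced; return (value, grad wrt logits/input))

def bce_with_logits(logits: np.ndarray, target: float):
    loss = float(np.mean(np.logaddexp(0.0, logits) - target * logits))
    sig = 1.0 / (1.0 + np.exp(-logits))
    grad = ((sig - target) / logits.size).astype(F32)
    return loss, grad


def l1_loss(pred: np.ndarray, target: np.ndarray):
    diff = pred - target
    loss = float(np.mean(np.abs(diff)))
    grad = (np.sign(diff) / diff.size).astype(F32)
    return loss, grad
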