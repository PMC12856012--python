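"""Minimal numpy neural-network ops: conv / transposed-conv layers with
manual backprop, ReLU/sigmoid, MSE loss and an Adam optimizer.

Convolutions are im2col-style (strided window views + einsum/BLAS), which
is plenty for 28x28 single-channel stacks at benchmark scale. All arrays
are float64; layouts follow the (N, C, H, W) convention.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "ConvTranspose2D",
    "ReLU",
    "Sigmoid",
    "Sequential",
    "Adam",
    "mse_loss",
]


def conv_out_size(size: int, kernel: int, stride: int, padding: int) -> int:
    return (size + 2 * padding - kernel) // stride + 1


def convt_out_size(
    size: int, kernel: int, stride: int, padding: int, output_padding: int = 0
) -> int:
    return (size - 1) * stride - 2 * padding + kernel + output_padding


def _windows(x: np.ndarray, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return v[:, :, ::stride, ::stride]


class Conv2D:
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, rng=None):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        bound = 1.0 / np.sqrt(fan_in)
        self.w = rng.uniform(-bound, bound, (out_ch, in_ch, kernel, kernel))
        self.b = rng.uniform(-bound, bound, out_ch)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        v = _windows(x, self.kernel, self.kernel, self.stride, self.padding)
        self._cache = (x.shape, v)
        out = np.einsum("nchwij,ocij->nohw", v, self.w, optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, v = self._cache
        self.dw[...] = np.einsum("nchwij,nohw->ocij", v, dy, optimize=True)
        self.db[...] = dy.sum(axis=(0, 2, 3))
        n, c, h, w = x_shape
        s, p, k = self.stride, self.padding, self.kernel
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        ho, wo = dy.shape[2], dy.shape[3]
        for i in range(k):
            for j in range(k):
                contrib = np.einsum("nohw,oc->nchw", dy, self.w[:, :, i, j],
                                    optimize=True)
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += contrib
        return dxp[:, :, p : p + h, p : p + w]


class ConvTranspose2D:
    """Transposed convolution; weight layout (in_ch, out_ch, k, k)."""

    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0,
                 output_padding=0, rng=None):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.padding, self.output_padding = padding, output_padding
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        bound = 1.0 / np.sqrt(fan_in)
        self.w = rng.uniform(-bound, bound, (in_ch, out_ch, kernel, kernel))
        self.b = rng.uniform(-bound, bound, out_ch)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p, op = self.kernel, self.stride, self.padding, self.output_padding
        ho = convt_out_size(h, k, s, p, op)
        wo = convt_out_size(w, k, s, p, op)
        full = np.zeros((n, self.out_ch, (h - 1) * s + k + op, (w - 1) * s + k + op))
        for i in range(k):
            for j in range(k):
                contrib = np.einsum("nchw,co->nohw", x, self.w[:, :, i, j],
                                    optimize=True)
                full[:, :, i : i + s * h : s, j : j + s * w : s] += contrib
        out = full[:, :, p : p + ho, p : p + wo]
        self._cache = x
        return out + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.padding
        v = _windows(dy, k, k, s, p)[:, :, :h, :w]
        self.dw[...] = np.einsum("nohwij,nchw->coij", v, x, optimize=True)
        self.db[...] = dy.sum(axis=(0, 2, 3))
        return np.einsum("nohwij,coij->nchw", v, self.w, optimize=True)


class ReLU:
    params: list = []

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Sigmoid:
    params: list = []

    def forward(self, x):
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, dy):
        return dy * self._out * (1.0 - self._out)


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        return out

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = 2.0 * diff / diff.size
    return loss, grad


class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, (p, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)


class SGD:
    def __init__(self, params, lr=1e-2):
        self.params = params
        self.lr = lr

    def step(self):
        for p, g in self.params:
            p -= self.lr * g
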