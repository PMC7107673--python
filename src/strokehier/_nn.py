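"""Minimal numpy building blocks for the segmentation network: padded 3x3/1x1
convolutions via im2col, 2x2 max pooling, nearest-neighbour upsampling, ReLU,
and Adam. Forward passes cache what backward needs; gradients accumulate into
``dW``/``db`` until ``zero_grad``.

Array layout is (N, C, H, W) throughout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "Adam", "relu", "relu_backward", "maxpool2", "maxpool2_backward",
           "upsample2", "upsample2_backward", "sigmoid"]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix for a stride-1, padded conv."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # (N, C, H, W, k, k) -> (N, C, k, k, H, W)
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + h, j:j + w] += d[:, :, i, j]
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad]
    return dxp


class Conv2D:
    """Stride-1 convolution with 'same' padding and He-normal init."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.cin, self.cout, self.k = cin, cout, ksize
        self.pad = ksize // 2
        fan_in = cin * ksize * ksize
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (cout, fan_in)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x.astype(self.W.dtype, copy=False), self.k, self.pad)
        self._cache = (x.shape, cols)
        y = np.einsum("of,nfl->nol", self.W, cols, optimize=True) + self.b[:, None]
        return y.reshape(n, self.cout, h, w)

    def backward(self, g: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache
        n, c, h, w = x_shape
        g2 = g.reshape(n, self.cout, h * w).astype(self.W.dtype, copy=False)
        self.dW += np.einsum("nol,nfl->of", g2, cols, optimize=True)
        self.db += g2.sum(axis=(0, 2))
        dcols = np.einsum("of,nol->nfl", self.W, g2, optimize=True)
        return _col2im(dcols, x_shape, self.k, self.pad)

    def zero_grad(self) -> None:
        self.dW[...] = 0.0
        self.db[...] = 0.0

    def params_and_grads(self):
        yield self.W, self.dW
        yield self.b, self.db


def relu(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mask = x > 0
    return x * mask, mask


def relu_backward(g: np.ndarray, mask: np.ndarray) -> np.ndarray:
    return g * mask


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """2x2 max pooling; returns (pooled, argmax-in-window) for backward."""
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4
    )
    idx = xr.argmax(axis=-1)
    out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return out, idx


def maxpool2_backward(g: np.ndarray, idx: np.ndarray, x_shape: tuple) -> np.ndarray:
    n, c, h, w = x_shape
    dxr = np.zeros((n, c, h // 2, w // 2, 4), dtype=g.dtype)
    np.put_along_axis(dxr, idx[..., None], g[..., None], axis=-1)
    return dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(g: np.ndarray) -> np.ndarray:
    n, c, h, w = g.shape
    return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam over the parameters of a list of Conv2D layers."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for layer in layers for p, _ in layer.params_and_grads()]
        self.v = [np.zeros_like(p) for layer in layers for p, _ in layer.params_and_grads()]

    def step(self) -> None:
        self.t += 1
        i = 0
        for layer in self.layers:
            for p, g in layer.params_and_grads():
                self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
                self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
                mhat = self.m[i] / (1 - self.beta1**self.t)
                vhat = self.v[i] / (1 - self.beta2**self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
                i += 1

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()
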