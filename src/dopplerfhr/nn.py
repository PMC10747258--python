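"""Minimal NumPy neural-network layers with explicit backpropagation.

Implements exactly the building blocks the signal-quality VAE needs —
strided 1-D convolution, transposed convolution, batch normalization, ELU,
dense layers — plus the Adam optimizer.  Layers operate on ``(batch,
channels, length)`` arrays, cache what backward needs, and accumulate
parameter gradients in ``.grads``; analytic gradients are verified against
finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np


def _im2col(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B, C, Lp) -> (B, C*k, Lo) patch matrix for a strided correlation."""
    b, c, lp = xp.shape
    lo = (lp - k) // stride + 1
    cols = np.empty((b, c, k, lo), dtype=xp.dtype)
    for kk in range(k):
        cols[:, :, kk, :] = xp[:, :, kk : kk + stride * lo : stride]
    return cols.reshape(b, c * k, lo)


def _col2im(cols: np.ndarray, c: int, k: int, stride: int, lp: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to (B, C, Lp)."""
    b, _, lo = cols.shape
    cols = cols.reshape(b, c, k, lo)
    xp = np.zeros((b, c, lp), dtype=cols.dtype)
    for kk in range(k):
        xp[:, :, kk : kk + stride * lo : stride] += cols[:, :, kk, :]
    return xp


class Layer:
    """Base class; subclasses define forward/backward and parameter lists."""

    params: dict[str, np.ndarray]
    grads: dict[str, np.ndarray]

    def __init__(self) -> None:
        self.params, self.grads = {}, {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """Strided 1-D convolution (cross-correlation), symmetric zero padding."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int, rng):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        scale = np.sqrt(2.0 / (c_in * k))
        self.params = {
            "W": rng.normal(0.0, scale, size=(c_out, c_in * k)),
            "b": np.zeros(c_out),
        }

    def forward(self, x, train=True):
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._cols, self._lp = _im2col(xp, self.k, self.stride), xp.shape[-1]
        return self.params["W"] @ self._cols + self.params["b"][:, None]

    def backward(self, dy):
        self.grads["b"] = dy.sum(axis=(0, 2))
        self.grads["W"] = np.tensordot(dy, self._cols, axes=([0, 2], [0, 2]))
        dcols = self.params["W"].T @ dy
        dxp = _col2im(dcols, self.c_in, self.k, self.stride, self._lp)
        return dxp[:, :, self.pad : dxp.shape[-1] - self.pad]


class ConvTranspose1d(Layer):
    """Strided transposed convolution; the exact adjoint of :class:`Conv1d`.

    With kernel 16, stride 2 and padding 7 the output length is exactly
    twice the input length, mirroring the encoder's halving.
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int, pad: int, rng):
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        scale = np.sqrt(2.0 / (c_in * k))
        self.params = {
            "W": rng.normal(0.0, scale, size=(c_in, c_out * k)),
            "b": np.zeros(c_out),
        }

    def out_len(self, l_in: int) -> int:
        return (l_in - 1) * self.stride - 2 * self.pad + self.k

    def forward(self, x, train=True):
        self._x = x
        lo = self.out_len(x.shape[-1])
        cols = self.params["W"].T @ x
        yp = _col2im(cols, self.c_out, self.k, self.stride, lo + 2 * self.pad)
        return yp[:, :, self.pad : self.pad + lo] + self.params["b"][:, None]

    def backward(self, dy):
        self.grads["b"] = dy.sum(axis=(0, 2))
        dyp = np.pad(dy, ((0, 0), (0, 0), (self.pad, self.pad)))
        dcols = _im2col(dyp, self.k, self.stride)
        self.grads["W"] = np.tensordot(self._x, dcols, axes=([0, 2], [0, 2]))
        return self.params["W"] @ dcols


class BatchNorm1d(Layer):
    """Per-channel batch normalization over (batch, length) with running stats."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)

    def forward(self, x, train=True):
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._invstd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[:, None]) * self._invstd[:, None]
        self._train = train
        return self.params["gamma"][:, None] * self._xhat + self.params["beta"][:, None]

    def backward(self, dy):
        self.grads["gamma"] = (dy * self._xhat).sum(axis=(0, 2))
        self.grads["beta"] = dy.sum(axis=(0, 2))
        dxhat = dy * self.params["gamma"][:, None]
        if not self._train:
            return dxhat * self._invstd[:, None]
        n = dy.shape[0] * dy.shape[2]
        return (
            self._invstd[:, None]
            / n
            * (
                n * dxhat
                - dxhat.sum(axis=(0, 2), keepdims=True)
                - self._xhat * (dxhat * self._xhat).sum(axis=(0, 2), keepdims=True)
            )
        )


class Elu(Layer):
    def forward(self, x, train=True):
        self._y = np.where(x > 0, x, np.expm1(x))
        return self._y

    def backward(self, dy):
        return dy * np.where(self._y > 0, 1.0, self._y + 1.0)


class Dense(Layer):
    """Affine map on (batch, features) arrays."""

    def __init__(self, n_in: int, n_out: int, rng):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.params = {"W": rng.normal(0.0, scale, size=(n_out, n_in)), "b": np.zeros(n_out)}

    def forward(self, x, train=True):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = dy.T @ self._x
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"]


class Adam:
    """Adam optimizer over the parameter dicts of a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers, self.lr, self.beta1, self.beta2, self.eps = layers, lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]
        self.v = [{k: np.zeros_like(v) for k, v in lay.params.items()} for lay in layers]

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for lay, m, v in zip(self.layers, self.m, self.v):
            for k, p in lay.params.items():
                g = lay.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1c) / (np.sqrt(v[k] / b2c) + self.eps)
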