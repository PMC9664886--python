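"""Layers with explicit forward/backward passes (NCHW, float32)."""

from __future__ import annotations

import numpy as np

__all__ = ["Param", "Layer", "Conv2d", "Upsample2x", "LeakyReLU", "ReLU",
           "Tanh", "InstanceNorm2d", "SpectralNorm", "Sequential"]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Layer:
    def params(self) -> list:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(xp: np.ndarray, k: int, stride: int):
    """Padded input (N,C,Hp,Wp) -> columns (N, C*k*k, Ho*Wo)."""
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # (N,C,Ho,Wo,k,k)
    n, c, ho, wo = win.shape[:4]
    cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, shape, k: int, stride: int, ho: int, wo: int):
    """Scatter-add columns back to the padded input layout."""
    n, c, hp, wp = shape
    dxp = np.zeros(shape, dtype=np.float32)
    d = dcols.reshape(n, c, k, k, ho, wo)
    for ki in range(k):
        for kj in range(k):
            dxp[:, :, ki:ki + stride * ho:stride, kj:kj + stride * wo:stride] += d[:, :, ki, kj]
    return dxp


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with 'same'-style padding.

    Padding k//2 keeps the spatial size for stride 1 and halves it exactly
    for stride 2 on even inputs (k in {3, 4}).
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 rng: np.random.Generator | None = None, init_std: float = 0.02):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride = k, stride
        self.c_in, self.c_out = c_in, c_out
        if k not in (1, 3, 4) or stride not in (1, 2):
            raise ValueError(f"unsupported kernel/stride combination k={k}, stride={stride}")
        self.pad = {1: 0, 3: 1, 4: 1}[k]
        self.weight = Param(rng.normal(0.0, init_std, size=(c_out, c_in * k * k)))
        self.bias = Param(np.zeros(c_out))
        self._cache = None

    def params(self):
        return [self.weight, self.bias]

    def _effective_weight(self, train: bool) -> np.ndarray:
        return self.weight.data

    def _weight_grad_hook(self, dw: np.ndarray) -> np.ndarray:
        return dw

    def forward(self, x, train: bool = True):
        x = np.ascontiguousarray(x, dtype=np.float32)
        p = self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols, ho, wo = _im2col(xp, self.k, self.stride)
        w = self._effective_weight(train)
        y = np.matmul(w, cols) + self.bias.data[None, :, None]
        self._cache = (cols, xp.shape, ho, wo, w)
        return y.reshape(x.shape[0], self.c_out, ho, wo)

    def backward(self, dy):
        cols, xp_shape, ho, wo, w = self._cache
        n = dy.shape[0]
        dyr = np.ascontiguousarray(dy, dtype=np.float32).reshape(n, self.c_out, ho * wo)
        dw = np.einsum("nfl,ncl->fc", dyr, cols, optimize=True)
        self.weight.grad += self._weight_grad_hook(dw)
        self.bias.grad += dyr.sum(axis=(0, 2))
        dcols = np.matmul(w.T, dyr)
        dxp = _col2im(dcols, xp_shape, self.k, self.stride, ho, wo)
        p = self.pad
        return dxp[:, :, p:dxp.shape[2] - p, p:dxp.shape[3] - p] if p else dxp


class SpectralNorm(Conv2d):
    """Convolution whose weight is divided by its spectral norm.

    One power iteration per training forward keeps a running estimate of the
    leading singular pair (u, v); the backward pass uses the full gradient of
    W / sigma, including the -(g . What) u v^T / sigma correction term.
    """

    def __init__(self, *args, **kwargs):
        super().__init__(*args, **kwargs)
        rng = np.random.default_rng(self.weight.data.size)
        self._u = rng.standard_normal(self.c_out).astype(np.float32)
        self._u /= np.linalg.norm(self._u)
        self._sn_cache = None

    def _power_iterate(self, train: bool):
        w = self.weight.data
        if train:
            v = w.T @ self._u
            v /= np.linalg.norm(v) + 1e-12
            u = w @ v
            u /= np.linalg.norm(u) + 1e-12
            self._u = u
        else:
            u = self._u
            v = w.T @ u
            v /= np.linalg.norm(v) + 1e-12
        sigma = float(u @ (w @ v))
        return u, v, max(abs(sigma), 1e-12)

    def spectral_sigma(self, iters: int = 30) -> float:
        """Accurate spectral norm of the *effective* (normalised) weight."""
        w = self.weight.data / getattr(self, "_last_sigma", 1.0)
        u = self._u.copy()
        v = w.T @ u
        for _ in range(iters):
            v = w.T @ u
            v /= np.linalg.norm(v) + 1e-12
            u = w @ v
            u /= np.linalg.norm(u) + 1e-12
        return abs(float(u @ (w @ v)))

    def _effective_weight(self, train: bool):
        u, v, sigma = self._power_iterate(train)
        self._sn_cache = (u, v, sigma)
        self._last_sigma = sigma
        return self.weight.data / sigma

    def _weight_grad_hook(self, dw):
        u, v, sigma = self._sn_cache
        w_bar = self.weight.data / sigma
        coef = float(np.sum(dw * w_bar))
        return (dw - coef * np.outer(u, v)) / sigma


class Upsample2x(Layer):
    """Nearest-neighbour 2x upsampling; backward sums 2x2 blocks."""

    def forward(self, x, train: bool = True):
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy):
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2):
        self.slope = slope
        self._mask = None

    def forward(self, x, train: bool = True):
        self._mask = x >= 0
        return np.where(self._mask, x, self.slope * x).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy).astype(np.float32)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(slope=0.0)


class Tanh(Layer):
    def forward(self, x, train: bool = True):
        self._y = np.tanh(x)
        return self._y

    def backward(self, dy):
        return (dy * (1.0 - self._y**2)).astype(np.float32)


class InstanceNorm2d(Layer):
    """Per-sample, per-channel normalisation with learned affine parameters."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train: bool = True):
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat.astype(np.float32), inv.astype(np.float32))
        return (self.gamma.data[None, :, None, None] * xhat
                + self.beta.data[None, :, None, None]).astype(np.float32)

    def backward(self, dy):
        xhat, inv = self._cache
        m = dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma.data[None, :, None, None]
        term = (dxhat - dxhat.mean(axis=(2, 3), keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=(2, 3), keepdims=True))
        return (term * inv).astype(np.float32)


class Sequential(Layer):
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, train: bool = True):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy
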