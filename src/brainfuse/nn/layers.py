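"""Minimal CPU layer zoo with explicit forward/backward passes.

All image tensors are NCHW float64. Each layer exposes

* ``init_params(rng)``      -> dict of parameter arrays (may be empty)
* ``forward(params, x, train)``  -> (y, cache)
* ``backward(params, cache, dy)`` -> (dx, grads-dict)

Layers are stateless between calls except for BatchNorm's running
moments, which live in the parameter dict so they persist with the
model (they receive no gradient).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "BatchNorm2D",
    "Activation",
    "MaxPool2D",
    "GlobalAvgPool",
    "AdaptiveAvgPool2D",
    "Upsample2x",
    "Flatten",
    "Reshape",
    "Dense",
    "Add",
]


def _windows(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """View of sliding (kh, kw) windows, shape (N, C, OH, OW, kh, kw)."""
    w = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return w[:, :, ::stride, ::stride]


class Conv2D:
    """2-D convolution with 'same'-style symmetric zero padding.

    Weight layout (C_out, C_in, kh, kw); He-normal initialisation.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1):
        self.in_ch = in_ch
        self.out_ch = out_ch
        self.kernel = kernel
        self.stride = stride
        # symmetric padding that reproduces the usual 'same' plan:
        # out = ceil(in / stride) for odd kernels
        self.pad = kernel // 2

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel, self.stride, self.pad
        return ((h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1)

    def init_params(self, rng: np.random.Generator) -> dict:
        fan_in = self.in_ch * self.kernel * self.kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(self.out_ch, self.in_ch, self.kernel, self.kernel))
        return {"w": w, "b": np.zeros(self.out_ch)}

    def forward(self, params, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = _windows(xp, k, k, s)                      # (N,C,OH,OW,k,k)
        oh, ow = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * k * k)
        wf = params["w"].reshape(self.out_ch, -1)
        y = cols @ wf.T + params["b"]
        y = y.reshape(n, oh, ow, self.out_ch).transpose(0, 3, 1, 2)
        return y, (cols, x.shape, (oh, ow))

    def backward(self, params, cache, dy):
        cols, xshape, (oh, ow) = cache
        n, c, h, w = xshape
        k, s, p = self.kernel, self.stride, self.pad
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * oh * ow, self.out_ch)
        wf = params["w"].reshape(self.out_ch, -1)
        dw = (dyf.T @ cols).reshape(params["w"].shape)
        db = dyf.sum(axis=0)
        dcols = (dyf @ wf).reshape(n, oh, ow, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki:ki + s * oh:s, kj:kj + s * ow:s] += (
                    dcols[:, :, :, :, ki, kj].transpose(0, 3, 1, 2))
        dx = dxp[:, :, p:p + h, p:p + w] if p else dxp
        return dx, {"w": dw, "b": db}


class BatchNorm2D:
    """Per-channel batch normalisation; running moments used at eval."""

    eps = 1e-5
    momentum = 0.9

    def __init__(self, ch: int):
        self.ch = ch

    def init_params(self, rng):
        return {
            "gamma": np.ones(self.ch),
            "beta": np.zeros(self.ch),
            "running_mean": np.zeros(self.ch),
            "running_var": np.ones(self.ch),
        }

    def forward(self, params, x, train=False):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            params["running_mean"][:] = (self.momentum * params["running_mean"]
                                         + (1 - self.momentum) * mean)
            params["running_var"][:] = (self.momentum * params["running_var"]
                                        + (1 - self.momentum) * var)
        else:
            mean = params["running_mean"]
            var = params["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None, None]) * inv_std[:, None, None]
        y = params["gamma"][:, None, None] * xhat + params["beta"][:, None, None]
        return y, (xhat, inv_std, x.shape, train)

    def backward(self, params, cache, dy):
        xhat, inv_std, xshape, train = cache
        n, c, h, w = xshape
        m = n * h * w
        dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        dbeta = dy.sum(axis=(0, 2, 3))
        g = params["gamma"][:, None, None]
        if not train:
            return dy * g * inv_std[:, None, None], {"gamma": dgamma, "beta": dbeta}
        dxhat = dy * g
        dx = (inv_std[:, None, None] / m) * (
            m * dxhat
            - dxhat.sum(axis=(0, 2, 3))[:, None, None]
            - xhat * (dxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        )
        return dx, {"gamma": dgamma, "beta": dbeta}


class Activation:
    """Elementwise nonlinearity: relu, sigmoid, or linear."""

    def __init__(self, kind: str):
        if kind not in ("relu", "sigmoid", "linear"):
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def init_params(self, rng):
        return {}

    def forward(self, params, x, train=False):
        if self.kind == "relu":
            y = np.maximum(x, 0.0)
        elif self.kind == "sigmoid":
            y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        else:
            y = x
        return y, y

    def backward(self, params, cache, dy):
        y = cache
        if self.kind == "relu":
            dx = dy * (y > 0)
        elif self.kind == "sigmoid":
            dx = dy * y * (1.0 - y)
        else:
            dx = dy
        return dx, {}


class MaxPool2D:
    def __init__(self, kernel: int = 2, stride: int = 2, pad: int = 0):
        self.kernel = kernel
        self.stride = stride
        self.pad = pad

    def out_shape(self, h, w):
        k, s, p = self.kernel, self.stride, self.pad
        return ((h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1)

    def init_params(self, rng):
        return {}

    def forward(self, params, x, train=False):
        n, c, h, w = x.shape
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)),
                    constant_values=-np.inf) if p else x
        win = _windows(xp, k, k, s)                      # (N,C,OH,OW,k,k)
        oh, ow = win.shape[2], win.shape[3]
        flat = win.reshape(n, c, oh, ow, k * k)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        return y, (idx, x.shape, (oh, ow))

    def backward(self, params, cache, dy):
        idx, xshape, (oh, ow) = cache
        n, c, h, w = xshape
        k, s, p = self.kernel, self.stride, self.pad
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        ki, kj = np.divmod(idx, k)                       # within-window offsets
        ni, ci, oi, oj = np.indices(idx.shape)
        rows = oi * s + ki
        cols = oj * s + kj
        np.add.at(dxp, (ni, ci, rows, cols), dy)
        dx = dxp[:, :, p:p + h, p:p + w] if p else dxp
        return dx, {}


class GlobalAvgPool:
    """(N, C, H, W) -> (N, C) spatial mean."""

    def init_params(self, rng):
        return {}

    def forward(self, params, x, train=False):
        return x.mean(axis=(2, 3)), x.shape

    def backward(self, params, cache, dy):
        n, c, h, w = cache
        return np.broadcast_to(dy[:, :, None, None] / (h * w), (n, c, h, w)).copy(), {}


class AdaptiveAvgPool2D:
    """Average-pool to a g x g output grid (requires H, W divisible by g)."""

    def __init__(self, grid: int):
        self.grid = grid

    def init_params(self, rng):
        return {}

    def forward(self, params, x, train=False):
        n, c, h, w = x.shape
        g = self.grid
        if h % g or w % g:
            raise ValueError(f"spatial dims ({h},{w}) not divisible by grid {g}")
        bh, bw = h // g, w // g
        y = x.reshape(n, c, g, bh, g, bw).mean(axis=(3, 5))
        return y, (x.shape, bh, bw)

    def backward(self, params, cache, dy):
        (n, c, h, w), bh, bw = cache
        g = self.grid
        dx = np.broadcast_to(
            dy[:, :, :, None, :, None] / (bh * bw), (n, c, g, bh, g, bw))
        return dx.reshape(n, c, h, w).copy(), {}


class Upsample2x:
    """Nearest-neighbour 2x spatial upsampling."""

    def init_params(self, rng):
        return {}

    def forward(self, params, x, train=False):
        y = np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)
        return y, x.shape

    def backward(self, params, cache, dy):
        n, c, h, w = cache
        return dy.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)), {}


class Flatten:
    def init_params(self, rng):
        return {}

    def forward(self, params, x, train=False):
        return x.reshape(x.shape[0], -1), x.shape

    def backward(self, params, cache, dy):
        return dy.reshape(cache), {}


class Reshape:
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape  # per-sample target shape

    def init_params(self, rng):
        return {}

    def forward(self, params, x, train=False):
        return x.reshape((x.shape[0],) + self.shape), x.shape

    def backward(self, params, cache, dy):
        return dy.reshape(cache), {}


class Dense:
    def __init__(self, in_dim: int, out_dim: int):
        self.in_dim = in_dim
        self.out_dim = out_dim

    def init_params(self, rng):
        w = rng.normal(0.0, np.sqrt(2.0 / self.in_dim),
                       size=(self.in_dim, self.out_dim))
        return {"w": w, "b": np.zeros(self.out_dim)}

    def forward(self, params, x, train=False):
        return x @ params["w"] + params["b"], x

    def backward(self, params, cache, dy):
        x = cache
        return dy @ params["w"].T, {"w": x.T @ dy, "b": dy.sum(axis=0)}


class Add:
    """Residual join of two equal-shape inputs; handled by the graph."""

    def init_params(self, rng):
        return {}

    def forward(self, params, xs, train=False):
        return xs[0] + xs[1], None

    def backward(self, params, cache, dy):
        return (dy, dy), {}
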