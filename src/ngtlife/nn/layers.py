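"""Layer primitives with explicit forward/backward passes.

Tensors are NCHW for spatial layers and (N, features) for dense layers.
Each layer stores its parameters in ``params`` and, after ``backward``,
matching gradients in ``grads``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x, train: bool = False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2D(Layer):
    """3x3 (or k x k) stride-1 same-padding convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k = c_in, c_out, k
        std = np.sqrt(2.0 / (c_in * k * k))
        self.params["W"] = rng.normal(0.0, std, size=(c_out, c_in * k * k)).astype(dtype)
        self.params["b"] = np.zeros(c_out, dtype=dtype)
        self._cache = None

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N, H, W, C, k, k) -> (N*H*W, C*k*k)
        cols = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        cols = np.ascontiguousarray(cols)
        out = cols @ self.params["W"].T + self.params["b"]
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout):
        cols, (n, c, h, w) = self._cache
        p, k = self.k // 2, self.k
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.grads["W"] = (dflat.T @ cols).astype(self.params["W"].dtype)
        self.grads["b"] = dflat.sum(axis=0).astype(self.params["b"].dtype)
        dcols = (dflat @ self.params["W"]).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=dout.dtype)
        for u in range(k):
            for v in range(k):
                dxp[:, :, u:u + h, v:v + w] += dcols[:, :, :, :, u, v].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x, train: bool = False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd sides are padded with -inf."""

    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x, train: bool = False):
        n, c, h, w = x.shape
        ph, pw = h % 2, w % 2
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), constant_values=-np.inf)
            h, w = h + ph, w + pw
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # break ties: keep only the first max in each window
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        mask = (flat & first).reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = (mask, (n, c, h, w), (ph, pw))
        return out

    def backward(self, dout):
        mask, (n, c, h, w), (ph, pw) = self._cache
        dx = (mask * dout[:, :, :, None, :, None]).reshape(n, c, h, w)
        if ph or pw:
            dx = dx[:, :, : h - ph, : w - pw]
        return dx


class GlobalAvgPool(Layer):
    """Spatial mean: (N, C, H, W) -> (N, C); the latent embedding layer."""

    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x, train: bool = False):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], (n, c, h, w)) / (h * w)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / n_in)
        self.params["W"] = rng.normal(0.0, std, size=(n_in, n_out)).astype(dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)
        self._x = None

    def forward(self, x, train: bool = False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = (self._x.T @ dout).astype(self.params["W"].dtype)
        self.grads["b"] = dout.sum(axis=0).astype(self.params["b"].dtype)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng=None):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train: bool = False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask
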