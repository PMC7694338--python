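"""Differentiable layers: valid convolution, 2x2 pooling, dense, ReLU.

All layers operate on ``(N, C, H, W)`` batches (dense layers on ``(N, d)``),
cache what backward needs during forward, and accumulate parameter
gradients in ``.grads`` aligned with ``.params``. Convolution is unpadded
("valid") with stride 1 and is computed by im2col + matrix multiply;
pooling is 2x2 stride 2 with floor semantics (a trailing odd row/column is
dropped). A pooling layer whose input spatial dimension is already 1 acts
as identity, which keeps the fixed layer stack applicable to very small
tiles.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "Pool2x2", "ReLULayer", "Flatten", "Dense"]


class Layer:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2D(Layer):
    """Valid 5x5 (or kxk) convolution, stride 1.

    Weights ``W`` have shape ``(n_filters, in_channels, k, k)`` and are
    initialised uniform Xavier/Glorot; biases start at zero.
    """

    def __init__(
        self,
        in_channels: int,
        n_filters: int,
        kernel: int,
        rng: np.random.Generator,
        dtype=np.float32,
    ):
        fan_in = in_channels * kernel * kernel
        fan_out = n_filters * kernel * kernel
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.W = rng.uniform(-limit, limit, (n_filters, in_channels, kernel, kernel)).astype(dtype)
        self.b = np.zeros(n_filters, dtype=dtype)
        self.kernel = kernel
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        k = self.kernel
        n, c, h, w = x.shape
        ho, wo = h - k + 1, w - k + 1
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # (N,C,Ho,Wo,k,k)
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * k * k)
        cols = np.ascontiguousarray(cols)
        wmat = self.W.reshape(self.W.shape[0], -1)
        out = cols @ wmat.T + self.b
        self._cache = (cols, x.shape)
        return out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, c, h, w = x_shape
        k = self.kernel
        f = self.W.shape[0]
        ho, wo = h - k + 1, w - k + 1
        dmat = dout.transpose(0, 2, 3, 1).reshape(-1, f)
        self.grads[0][...] = (dmat.T @ cols).reshape(self.W.shape)
        self.grads[1][...] = dmat.sum(axis=0)
        dcols = (dmat @ self.W.reshape(f, -1)).reshape(n, ho, wo, c, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (N,C,Ho,Wo,k,k)
        dx = np.zeros(x_shape, dtype=dout.dtype)
        for i in range(k):
            for j in range(k):
                dx[:, :, i : i + ho, j : j + wo] += dcols[:, :, :, :, i, j]
        return dx


class Pool2x2(Layer):
    """2x2 stride-2 pooling, max (default) or average.

    Floor semantics: an odd trailing row/column receives no gradient and
    contributes nothing. Identity when the input spatial extent is < 2.
    """

    def __init__(self, mode: str = "max"):
        if mode not in ("max", "average"):
            raise ValueError(f"unknown pooling mode {mode!r}")
        self.mode = mode
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if min(h, w) < 2:
            self._cache = ("identity", x.shape)
            return x
        h2, w2 = h // 2, w // 2
        r = x[:, :, : 2 * h2, : 2 * w2].reshape(n, c, h2, 2, w2, 2)
        quads = r.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        if self.mode == "max":
            idx = np.argmax(quads, axis=-1)
            out = np.take_along_axis(quads, idx[..., None], axis=-1)[..., 0]
            self._cache = ("max", x.shape, idx)
        else:
            out = quads.mean(axis=-1)
            self._cache = ("average", x.shape, None)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        kind, x_shape = self._cache[0], self._cache[1]
        if kind == "identity":
            return dout
        n, c, h, w = x_shape
        h2, w2 = h // 2, w // 2
        dquads = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        if kind == "max":
            idx = self._cache[2]
            np.put_along_axis(dquads, idx[..., None], dout[..., None], axis=-1)
        else:
            dquads[...] = (dout / 4.0)[..., None]
        dx = np.zeros(x_shape, dtype=dout.dtype)
        dx[:, :, : 2 * h2, : 2 * w2] = (
            dquads.reshape(n, c, h2, w2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, 2 * h2, 2 * w2)
        )
        return dx


class ReLULayer(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(x.dtype)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0).astype(dout.dtype)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer: out = x W + b."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, dtype=np.float32):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = rng.uniform(-limit, limit, (n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T
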