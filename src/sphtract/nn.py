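"""Minimal pure-numpy 2D neural-network layers with explicit backpropagation.

Implements exactly what the segmentation backbone needs: 3x3 same-padding
convolution, leaky ReLU, 2x2 max pooling, 2x2-stride-2 transposed convolution,
inverted dropout and an Adam optimizer.  Data layout is (B, C, H, W) float32.
Each layer caches what its backward pass needs; ``backward`` consumes the
gradient w.r.t. its output and accumulates parameter gradients in ``dW``/``db``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class; stateless layers override forward/backward only."""

    def params(self) -> list[tuple[str, np.ndarray, np.ndarray]]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, stride 1, zero same-padding."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        scale = np.sqrt(2.0 / fan_in)  # He init for (leaky) ReLU stacks
        self.W = rng.normal(0.0, scale, size=(c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def n_params(self) -> int:
        return self.W.size + self.b.size

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k, p = self.k, self.k // 2
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(x, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
        B, C, H, W = win.shape[:4]
        return win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * k * k)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        B, C, H, W = x.shape
        cols = self._im2col(x)
        out = cols @ self.W.T + self.b
        if training:
            self._cols, self._shape = cols, (B, C, H, W)
        return out.reshape(B, H, W, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        self.dW += dflat.T @ self._cols
        self.db += dflat.sum(axis=0)
        # grad w.r.t. input of a same-padding stride-1 conv = same conv of dout
        # with spatially flipped kernels and in/out channels swapped
        Wk = self.W.reshape(self.c_out, self.c_in, self.k, self.k)
        Wflip = Wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
            self.c_in, self.c_out * self.k * self.k
        )
        tmp = Conv2d.__new__(Conv2d)
        tmp.c_in, tmp.c_out, tmp.k = self.c_out, self.c_in, self.k
        tmp.W, tmp.b = Wflip, np.zeros(self.c_in, dtype=np.float32)
        dx = tmp.forward(dout, training=False)
        self._cols = None
        return dx


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False):
        neg = x < 0
        if training:
            self._mask = neg
        return np.where(neg, self.slope * x, x)

    def backward(self, dout):
        return np.where(self._mask, self.slope * dout, dout)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; gradient routed to the (first) argmax."""

    def forward(self, x, training=False):
        B, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {H}x{W}")
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(B, C, H // 2, W // 2, 4)
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx, self._in_shape = idx, (B, C, H, W)
        return out

    def backward(self, dout):
        B, C, H, W = self._in_shape
        d = np.zeros((B, C, H // 2, W // 2, 4), dtype=dout.dtype)
        np.put_along_axis(d, self._idx[..., None], dout[..., None], axis=-1)
        d = d.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return d.reshape(B, C, H, W)


class ConvTranspose2d(Layer):
    """2x2 transposed convolution with stride 2 (exact 2x upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        self.c_in, self.c_out = c_in, c_out
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / c_in)
        self.W = rng.normal(0.0, scale, size=(c_in, c_out, 2, 2)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [("W", self.W, self.dW), ("b", self.b, self.db)]

    def n_params(self) -> int:
        return self.W.size + self.b.size

    def forward(self, x, training=False):
        B, C, H, W = x.shape
        if training:
            self._x = x
        y = np.einsum("bcij,cdpq->bdipjq", x, self.W, optimize=True)
        y = y.reshape(B, self.c_out, 2 * H, 2 * W)
        return y + self.b[None, :, None, None]

    def backward(self, dout):
        B = dout.shape[0]
        H2, W2 = dout.shape[2], dout.shape[3]
        blocks = dout.reshape(B, self.c_out, H2 // 2, 2, W2 // 2, 2)
        self.db += dout.sum(axis=(0, 2, 3))
        self.dW += np.einsum("bcij,bdipjq->cdpq", self._x, blocks, optimize=True)
        dx = np.einsum("bdipjq,cdpq->bcij", blocks, self.W, optimize=True)
        self._x = None
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask: np.ndarray | None = None

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Adam:
    """Adam over a flat list of (value, grad) array pairs."""

    def __init__(self, params: list[tuple[str, np.ndarray, np.ndarray]],
                 lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(v) for _, v, _ in params]
        self.v = [np.zeros_like(v) for _, v, _ in params]

    def zero_grad(self) -> None:
        for _, _, g in self.params:
            g[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for i, (_, val, grad) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            val -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
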