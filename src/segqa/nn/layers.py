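"""Building-block layers with explicit forward/backward passes.

Convolutions are stride-1, 'same'-padded, implemented as im2col matrix
multiplications; the backward pass for the input is the full correlation of
the upstream gradient with the spatially flipped kernels, again as im2col.
Each layer caches what its own backward needs; a layer instance is used once
per forward pass.

Spatial concrete dropout drops whole feature channels through a continuously
relaxed Bernoulli mask with a learnable dropout probability p per layer:

    z = sigmoid((logit(p) + logit(u)) / t),  u ~ Uniform(0, 1),
    out = x * (1 - z) / (1 - p),

so gradients flow into p (parameterized as p = sigmoid(rho), keeping p in
(0, 1) throughout training).  At temperature t -> 0 the mask hardens to
Bernoulli(p) channel dropout; the inverted scaling keeps E[out] ~ x, so the
deterministic pass is the identity.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Param:
    """A trainable array with its gradient and Adam moment buffers."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.m = np.zeros_like(self.value)
        self.v = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) -> (B*H*W, C*k*k) patches under same-padding."""
    if k == 1:
        B, C, H, W = x.shape
        return x.transpose(0, 2, 3, 1).reshape(B * H * W, C)
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B, C, H, W, k, k)
    B, C, H, W = x.shape
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * k * k)


class Conv2d:
    """Stride-1 same-padding convolution, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))
        self.k = k
        self.cin, self.cout = cin, cout
        self.W = Param(rng.normal(0.0, scale, size=(cout, cin, k, k)))
        self.b = Param(np.zeros(cout))
        self._cols: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        cols = _im2col(x, self.k)
        y = cols @ self.W.value.reshape(self.cout, -1).T + self.b.value
        if train:
            self._cols, self._shape = cols, (B, C, H, W)
        return y.reshape(B, H, W, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(B * H * W, self.cout)
        self.W.grad += (dyf.T @ self._cols).reshape(self.W.value.shape)
        self.b.grad += dyf.sum(axis=0)
        # dX = full-correlation of dy with flipped kernels
        Wflip = self.W.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.cin, -1)
        dy_cols = _im2col(dy, self.k)
        dx = (dy_cols @ Wflip.T).reshape(B, H, W, self.cin).transpose(0, 3, 1, 2)
        self._cols = None
        return dx


class LeakyReLU:
    def __init__(self, slope: float = 1e-2):
        self.slope = slope
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dy, self.slope * dy)
        self._mask = None
        return dx


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


class SpatialConcreteDropout:
    """Channel-wise concrete dropout with a learnable probability per layer."""

    def __init__(self, init_p: float, temperature: float = 0.1):
        if not 0.0 < init_p < 1.0:
            raise ValueError("init_p must lie in (0, 1)")
        self.rho = Param(np.array(_logit(init_p)))
        self.temperature = temperature
        self._cache: tuple | None = None

    @property
    def p(self) -> float:
        return float(1.0 / (1.0 + np.exp(-self.rho.value)))

    def params(self):
        return [self.rho]

    def forward(
        self,
        x: np.ndarray,
        rng: np.random.Generator | None = None,
        stochastic: bool = True,
        train: bool = True,
    ) -> np.ndarray:
        if not stochastic:
            return x  # inverted scaling makes the deterministic pass the identity
        if rng is None:
            raise ValueError("stochastic forward requires an rng")
        B, C = x.shape[:2]
        p = self.p
        u = rng.uniform(1e-7, 1.0 - 1e-7, size=(B, C, 1, 1)).astype(DTYPE)
        eta = (_logit(p) + np.log(u) - np.log1p(-u)) / self.temperature
        z = 1.0 / (1.0 + np.exp(-np.clip(eta, -60.0, 60.0)))
        keep = (1.0 - z) / (1.0 - p)
        if train:
            self._cache = (x, z, keep, p)
        return x * keep

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:  # deterministic pass
            return dy
        x, z, keep, p = self._cache
        dx = dy * keep
        # d[(1-z)/(1-p)]/drho with p = sigmoid(rho):
        #   dz/drho = z(1-z)/t,  dp/drho = p(1-p)
        #   => ds/drho = (1-z) * (p - z/t) / (1-p)
        ds_drho = (1.0 - z) * (p - z / self.temperature) / (1.0 - p)
        self.rho.grad += float(np.sum(dy * x * ds_drho))
        self._cache = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2."""

    def __init__(self):
        self._cache: tuple | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(B, C, H // 2, W // 2, 4)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (B, C, H, W))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (B, C, H, W) = self._cache
        flat = np.zeros((B, C, H // 2, W // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, idx[..., None], dy[..., None], axis=-1)
        dx = flat.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._cache = None
        return dx.reshape(B, C, H, W)


class UpsampleNearest2:
    """2x nearest-neighbour upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, H, W = dy.shape
        return dy.reshape(B, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))
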