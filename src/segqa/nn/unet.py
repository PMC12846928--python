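"""2D U-Net with spatial concrete dropout after every convolution.

Encoder/decoder with ``levels`` resolution stages; channel count doubles per
encoder level from ``base_channels`` (5 levels x 30 channels gives the
full-scale 480-channel bottleneck; the desk default of 3 levels x 28 channels
gives 112).  Every 3x3 convolution in encoder and decoder is followed by a
leaky ReLU and a spatial concrete-dropout mask with its own learnable dropout
probability; the final 1x1 projection to class scores carries no dropout and
feeds a per-pixel softmax.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    DTYPE,
    Conv2d,
    LeakyReLU,
    MaxPool2,
    SpatialConcreteDropout,
    UpsampleNearest2,
)


class ConvBlock:
    """conv 3x3 -> leaky ReLU -> spatial concrete dropout."""

    def __init__(self, cin: int, cout: int, leaky_slope: float, init_p: float,
                 temperature: float, rng: np.random.Generator):
        self.conv = Conv2d(cin, cout, 3, rng)
        self.act = LeakyReLU(leaky_slope)
        self.drop = SpatialConcreteDropout(init_p, temperature)

    def params(self):
        return self.conv.params() + self.drop.params()

    def forward(self, x, rng=None, stochastic=True, train=True):
        x = self.conv.forward(x, train)
        x = self.act.forward(x, train)
        return self.drop.forward(x, rng=rng, stochastic=stochastic, train=train)

    def backward(self, dy):
        return self.conv.backward(self.act.backward(self.drop.backward(dy)))


class UNet:
    """Stochastic multi-class segmentation network.

    Maps a (B, 1, H, W) grayscale batch to (B, C, H, W) per-pixel softmax
    scores.  H and W must be divisible by 2**(levels-1).
    """

    def __init__(self, config, rng: np.random.Generator):
        from ..model import ModelConfig  # noqa: F401  (type of `config`)

        self.config = config
        self.checkpoint_id: str | None = None
        L, F = config.levels, config.base_channels
        lo, hi = config.dropout_init_range
        t = config.concrete_temperature

        def block(cin, cout):
            return ConvBlock(cin, cout, config.leaky_slope,
                             float(rng.uniform(lo, hi)), t, rng)

        self.enc: list[list[ConvBlock]] = []
        cin = 1
        for i in range(L - 1):
            cout = F * 2**i
            self.enc.append([block(cin, cout), block(cout, cout)])
            cin = cout
        cbot = F * 2 ** (L - 1)
        self.bottleneck = [block(cin, cbot), block(cbot, cbot)]
        self.pools = [MaxPool2() for _ in range(L - 1)]
        self.ups = [UpsampleNearest2() for _ in range(L - 1)]
        self.dec: list[list[ConvBlock]] = []
        for i in reversed(range(L - 1)):
            skip_c, up_c = F * 2**i, F * 2 ** (i + 1)
            self.dec.append([block(skip_c + up_c, skip_c), block(skip_c, skip_c)])
        self.head = Conv2d(cin if L == 1 else F, config.class_count, 1, rng)
        self._skip_channels = [F * 2**i for i in range(L - 1)]

    # -- parameter access ---------------------------------------------------
    def blocks(self):
        for stage in self.enc:
            yield from stage
        yield from self.bottleneck
        for stage in self.dec:
            yield from stage

    def params(self):
        out = []
        for b in self.blocks():
            out.extend(b.params())
        out.extend(self.head.params())
        return out

    def dropout_probabilities(self) -> list[float]:
        """Learned dropout probability of every conv block, encoder to decoder."""
        return [b.drop.p for b in self.blocks()]

    @property
    def bottleneck_channels(self) -> int:
        return self.bottleneck[-1].conv.cout

    # -- passes -------------------------------------------------------------
    def _check_shape(self, x: np.ndarray) -> None:
        div = 2 ** (self.config.levels - 1)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("input must be (B, 1, H, W)")
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"image size {x.shape[2:]} not divisible by 2^(levels-1) = {div}"
            )

    def forward(self, x: np.ndarray, rng=None, stochastic=True, train=True) -> np.ndarray:
        """Class logits (B, C, H, W)."""
        self._check_shape(x)
        x = np.ascontiguousarray(x, dtype=DTYPE)
        skips = []
        for stage, pool in zip(self.enc, self.pools):
            for b in stage:
                x = b.forward(x, rng, stochastic, train)
            skips.append(x)
            x = pool.forward(x, train)
        for b in self.bottleneck:
            x = b.forward(x, rng, stochastic, train)
        for stage, up, skip in zip(self.dec, self.ups, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            for b in stage:
                x = b.forward(x, rng, stochastic, train)
        return self.head.forward(x, train)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.head.backward(dlogits)
        dskips = []  # gradient w.r.t. skip i, collected shallow-to-deep
        for stage, up in zip(reversed(self.dec), reversed(self.ups)):
            for b in reversed(stage):
                g = b.backward(g)
            c = self._skip_channels[len(dskips)]
            dskips.append(g[:, :c])
            g = up.backward(g[:, c:])
        for b in reversed(self.bottleneck):
            g = b.backward(g)
        for stage, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                      reversed(dskips)):
            g = pool.backward(g) + dskip
            for b in reversed(stage):
                g = b.backward(g)

    def predict_probs(self, x: np.ndarray, stochastic: bool = False,
                      rng: np.random.Generator | None = None) -> np.ndarray:
        """Per-pixel softmax probabilities (float64, renormalized)."""
        logits = self.forward(x, rng=rng, stochastic=stochastic, train=False)
        return softmax(logits.astype(np.float64), axis=1)


def softmax(logits: np.ndarray, axis: int) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
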