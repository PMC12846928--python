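"""Stochastic segmentation model: configuration, training, checkpointing.

The network is a 2D U-Net whose every convolution is followed by spatial
concrete dropout with a learnable per-layer dropout probability (see
:mod:`segqa.nn`).  Training minimizes per-pixel cross-entropy plus the
concrete-dropout regularizer

    sum_layers [ w_scale * ||W||^2 / (1 - p)  +  reg_scale * K * H_b(p) ],

with H_b the (negative) Bernoulli entropy and K the layer's channel count,
which is what lets each layer find its own dropout rate.  Optimization uses
Adam; left-right flipping is the only augmentation.  Scans are never split
across partitions: all slices of a scan land in train or in validation.

Two named configurations are provided: the full-scale architecture
(5 levels, 30 base channels, learning rate 1e-4) and a desk-scale default
(3 levels, 28 base channels, learning rate 3e-3) trainable on one CPU in
minutes.  The desk model is shallower but kept wide: channel-wise dropout
in very narrow layers makes single Monte Carlo samples lose whole features,
which caps the confidence of the ensemble mean; width restores the channel
redundancy the method relies on.  The larger step size compensates for the
desk cohort's far smaller number of optimizer steps.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn.unet import UNet, softmax
from .phantom import N_CLASSES


@dataclass(frozen=True)
class ModelConfig:
    levels: int = 3
    base_channels: int = 28
    convs_per_stage: int = 2
    leaky_slope: float = 1e-2
    class_count: int = N_CLASSES
    dropout_init_range: tuple[float, float] = (0.05, 0.15)
    concrete_temperature: float = 0.1
    dropout_reg_scale: float = 1e-5
    weight_reg_scale: float = 1e-6

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.class_count != N_CLASSES:
            raise ValueError(f"class_count must be {N_CLASSES}")
        lo, hi = self.dropout_init_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("dropout_init_range must lie inside (0, 1)")
        if self.convs_per_stage != 2:
            raise ValueError("only 2 convolutions per stage are supported")


#: The architecture at publication scale: 30 -> 480 channels over five levels.
FULL_SCALE = ModelConfig(levels=5, base_channels=30)


@dataclass(frozen=True)
class TrainConfig:
    """Training recipe.

    ``class_weighting`` rebalances the cross-entropy per ground-truth class:
    ``"sqrt_inverse_frequency"`` (desk default) weights class c by
    1/sqrt(freq_c), normalized to mean 1 over pixels, so the smallest
    structure (1-2% of pixels) is learned within the short desk-scale step
    budget; ``None`` is the plain unweighted loss of the full-scale recipe.
    """

    epochs: int = 20
    batch_size: int = 8
    learning_rate: float = 3e-3
    lr_schedule: str = "constant"  # or "cosine" decay to ~0
    flip_prob: float = 0.5
    loss: str = "cross_entropy"
    class_weighting: str | None = "sqrt_inverse_frequency"
    val_fraction: float = 0.2
    selection: str = "best_val"  # keep the epoch with lowest validation loss
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ValueError("flip_prob must lie in [0, 1]")
        if self.loss != "cross_entropy":
            raise ValueError("only cross_entropy loss is supported")
        if self.class_weighting not in (None, "inverse_frequency",
                                        "sqrt_inverse_frequency"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")
        if self.lr_schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")
        if self.selection not in ("best_val", "final"):
            raise ValueError(f"unknown selection {self.selection!r}")


def build_model(config: ModelConfig | None = None, seed: int = 0) -> UNet:
    """Construct an untrained stochastic predictor from a configuration."""
    return UNet(config or ModelConfig(), np.random.default_rng(seed))


@dataclass
class TrainResult:
    model: UNet
    loss_trace: list[float]
    val_loss_trace: list[float]
    dropout_probabilities: list[float]
    mean_dropout_probability: float
    train_scans: list[int] = field(default_factory=list)
    val_scans: list[int] = field(default_factory=list)


def cross_entropy(probs: np.ndarray, labels: np.ndarray,
                  class_weights: np.ndarray | None = None) -> float:
    """(Optionally class-weighted) mean per-pixel negative log-likelihood."""
    p_true = np.take_along_axis(probs, labels[:, None].astype(np.int64), axis=1)[:, 0]
    nll = -np.log(np.clip(p_true, 1e-12, None))
    if class_weights is None:
        return float(nll.mean())
    w = class_weights[labels]
    return float((w * nll).sum() / w.sum())


def _class_weights(cfg: TrainConfig, slices) -> np.ndarray | None:
    if cfg.class_weighting is None:
        return None
    counts = np.zeros(N_CLASSES)
    for _, msk in slices:
        counts += np.bincount(np.asarray(msk).ravel(), minlength=N_CLASSES)
    freq = counts / counts.sum()
    with np.errstate(divide="ignore"):
        w = np.where(freq > 0,
                     1.0 / freq if cfg.class_weighting == "inverse_frequency"
                     else 1.0 / np.sqrt(freq), 0.0)
    # normalize to mean weight 1 over pixels so the loss scale is comparable
    return w / (w * freq).sum()


def _split_scans(n_scans: int, val_fraction: float, rng: np.random.Generator):
    order = rng.permutation(n_scans)
    n_val = max(1, int(round(val_fraction * n_scans))) if n_scans > 1 else 0
    return sorted(order[n_val:].tolist()), sorted(order[:n_val].tolist())


def train(model: UNet, cohort, train_config: TrainConfig | None = None) -> TrainResult:
    """Train on a cohort of ``(volume, mask_volume)`` scans.

    The train/validation split is by scan, never by slice.  Raises
    ``FloatingPointError`` on a non-finite loss.
    """
    cfg = train_config or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    mcfg = model.config

    train_idx, val_idx = _split_scans(len(cohort), cfg.val_fraction, rng)
    train_slices = [(np.asarray(img), np.asarray(msk))
                    for i in train_idx
                    for img, msk in zip(*cohort[i])]
    val_slices = [(np.asarray(img), np.asarray(msk))
                  for i in val_idx
                  for img, msk in zip(*cohort[i])]
    if not train_slices:
        raise ValueError("cohort has no training scans")

    class_weights = _class_weights(cfg, train_slices)
    params = model.params()
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    batches_per_epoch = int(np.ceil(len(train_slices) / cfg.batch_size))
    total_steps = cfg.epochs * batches_per_epoch
    loss_trace, val_loss_trace = [], []

    for _epoch in range(cfg.epochs):
        order = rng.permutation(len(train_slices))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch_ids = order[start:start + cfg.batch_size]
            imgs = np.stack([train_slices[i][0] for i in batch_ids])[:, None]
            labels = np.stack([train_slices[i][1] for i in batch_ids])
            flip = rng.random(len(batch_ids)) < cfg.flip_prob
            imgs[flip] = imgs[flip, :, :, ::-1]
            labels[flip] = labels[flip, :, ::-1]

            for p in params:
                p.zero_grad()
            logits = model.forward(imgs, rng=rng, stochastic=True, train=True)
            probs = softmax(logits.astype(np.float64), axis=1)
            loss = cross_entropy(probs, labels, class_weights)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at step {step}")
            epoch_losses.append(loss)

            onehot = np.zeros_like(probs)
            np.put_along_axis(onehot, labels[:, None].astype(np.int64), 1.0, axis=1)
            if class_weights is None:
                npix = probs.shape[0] * probs.shape[2] * probs.shape[3]
                dlogits = (probs - onehot) / npix
            else:
                w_pix = class_weights[labels]
                dlogits = (probs - onehot) * (w_pix[:, None] / w_pix.sum())
            model.backward(dlogits.astype(np.float32))
            _add_dropout_regularizer_grads(model, mcfg)

            step += 1
            base_lr = cfg.learning_rate
            if cfg.lr_schedule == "cosine":
                base_lr *= 0.5 * (1 + np.cos(np.pi * (step - 1) / total_steps))
            lr_t = base_lr * np.sqrt(1 - beta2**step) / (1 - beta1**step)
            for p in params:
                p.m = beta1 * p.m + (1 - beta1) * p.grad
                p.v = beta2 * p.v + (1 - beta2) * p.grad**2
                p.value -= lr_t * p.m / (np.sqrt(p.v) + eps)

        loss_trace.append(float(np.mean(epoch_losses)))
        val_loss_trace.append(_validation_loss(model, val_slices, class_weights))
        if (cfg.selection == "best_val" and val_slices
                and val_loss_trace[-1] <= np.nanmin(val_loss_trace)):
            best_params = [p.value.copy() for p in params]

    if cfg.selection == "best_val" and val_slices:
        for p, best in zip(params, best_params):
            p.value[...] = best

    probs_per_layer = model.dropout_probabilities()
    if not all(0.0 < p < 1.0 for p in probs_per_layer):
        raise FloatingPointError("a dropout probability left (0, 1)")
    return TrainResult(
        model=model,
        loss_trace=loss_trace,
        val_loss_trace=val_loss_trace,
        dropout_probabilities=probs_per_layer,
        mean_dropout_probability=float(np.mean(probs_per_layer)),
        train_scans=train_idx,
        val_scans=val_idx,
    )


def _add_dropout_regularizer_grads(model: UNet, mcfg: ModelConfig) -> None:
    for block in model.blocks():
        p = block.drop.p
        W = block.conv.W
        W.grad += (2.0 * mcfg.weight_reg_scale / (1.0 - p)) * W.value
        K = block.conv.cout
        dreg_dp = (mcfg.weight_reg_scale * float(np.sum(W.value**2)) / (1.0 - p) ** 2
                   + mcfg.dropout_reg_scale * K * (np.log(p) - np.log1p(-p)))
        block.drop.rho.grad += dreg_dp * p * (1.0 - p)


def _validation_loss(model: UNet, val_slices, class_weights=None) -> float:
    if not val_slices:
        return float("nan")
    losses = []
    for img, msk in val_slices:
        probs = model.predict_probs(img[None, None], stochastic=False)
        losses.append(cross_entropy(probs, msk[None], class_weights))
    return float(np.mean(losses))


# ---------------------------------------------------------------------------
# Checkpointing — a self-describing npz with the config embedded as JSON
# ---------------------------------------------------------------------------


def save_checkpoint(model: UNet, path) -> None:
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> UNet:
    with open(path, "rb") as fh:
        data = np.load(io.BytesIO(fh.read()))
    if "config_json" not in data:
        raise ValueError(f"{path} is not a segqa checkpoint")
    cfg_dict = json.loads(bytes(data["config_json"]).decode())
    cfg_dict["dropout_init_range"] = tuple(cfg_dict["dropout_init_range"])
    model = build_model(ModelConfig(**cfg_dict), seed=0)
    for i, p in enumerate(model.params()):
        stored = data[f"param_{i}"]
        if stored.shape != p.value.shape:
            raise ValueError("checkpoint incompatible with its own config")
        p.value[...] = stored
    model.checkpoint_id = str(path)
    return model
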