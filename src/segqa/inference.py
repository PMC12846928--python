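"""Monte Carlo dropout inference: stochastic ensembles, mean prediction, binarization.

The stochastic predictor is passed T times over the input with dropout active;
each pass yields a per-pixel softmax over the four classes.  The model
prediction is the arithmetic mean over the T passes, binarized by taking the
highest-probability class per pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import CLASS_NAMES, N_CLASSES

DEFAULT_T = 50  # stochastic forward passes; accuracy stabilizes by this count


@dataclass
class PredictionEnsemble:
    """T stochastic per-pixel class-probability maps.

    ``samples`` has shape (T, C, H, W); sample t holds the softmax output of
    the network under the t-th dropout draw of the weights.
    """

    samples: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=np.float64)
        if s.ndim != 4:
            raise ValueError("samples must be (T, C, H, W)")
        if s.shape[0] < 1:
            raise ValueError("T must be >= 1")
        if s.shape[1] != N_CLASSES:
            raise ValueError(f"expected {N_CLASSES} classes, got {s.shape[1]}")
        if s.min() < -1e-12 or s.max() > 1 + 1e-12:
            raise ValueError("probabilities must lie in [0, 1]")
        sums = s.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-5:
            raise ValueError("each sample must sum to 1 per pixel (tol 1e-5)")
        self.samples = s

    @property
    def T(self) -> int:
        return self.samples.shape[0]

    @property
    def mean_probs(self) -> np.ndarray:
        """Sample-mean class probabilities, shape (C, H, W)."""
        return self.samples.mean(axis=0)


@dataclass
class MeanPrediction:
    """Averaged probabilities and their argmax binarization."""

    mean_probs: np.ndarray  # (C, H, W)
    label_mask: np.ndarray  # (H, W) uint8


def mean_and_binarize(ensemble: PredictionEnsemble) -> MeanPrediction:
    """Average over the T samples and binarize by highest class probability.

    Ties are broken toward the lowest class index (so background wins an
    all-way tie) — deterministic and conservative for error flagging.
    """
    mean = ensemble.mean_probs
    labels = np.argmax(mean, axis=0).astype(np.uint8)  # np.argmax: first max wins
    return MeanPrediction(mean_probs=mean, label_mask=labels)


def sample_ensemble(model, image: np.ndarray, T: int = DEFAULT_T, seed: int = 0) -> PredictionEnsemble:
    """Run T stochastic forward passes with dropout active at inference.

    ``model`` is a :class:`segqa.nn.unet.UNet`; passes are batched (the image
    is replicated T times with independent dropout masks per replicate) for
    speed.  Seed-reproducible.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("image must be 2D")
    rng = np.random.default_rng(seed)
    batch = np.broadcast_to(img[None, None], (T, 1) + img.shape).copy()
    probs = model.predict_probs(batch, stochastic=True, rng=rng)  # (T, C, H, W)
    return PredictionEnsemble(
        samples=probs,
        provenance={"source": "sample_ensemble", "T": T, "seed": seed,
                    "checkpoint": getattr(model, "checkpoint_id", None)},
    )


def sample_ensemble_volume(model, volume: np.ndarray, T: int = DEFAULT_T, seed: int = 0):
    """Per-slice ensembles for a (S, H, W) volume; returns a list of
    :class:`PredictionEnsemble`, one per slice, with independent substreams."""
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("volume must be (S, H, W)")
    children = np.random.SeedSequence(seed).spawn(vol.shape[0])
    out = []
    for sl, child in zip(vol, children):
        rng = np.random.default_rng(child)
        batch = np.broadcast_to(sl[None, None], (T, 1) + sl.shape).copy()
        probs = model.predict_probs(batch, stochastic=True, rng=rng)
        out.append(PredictionEnsemble(samples=probs,
                                      provenance={"source": "sample_ensemble_volume",
                                                  "T": T, "seed": seed}))
    return out
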