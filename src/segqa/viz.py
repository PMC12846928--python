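"""Uncertainty-map rendering and four-shade error flagging.

The flag map partitions pixels into four categories from the predicted label,
a per-class (or total) predictive-entropy map and a PE threshold (default
0.30): *uncertain positive* (predicted as the structure but with high PE — a
potential false positive, darkest shade), *uncertain negative* (predicted as
background/other with high PE — a potential false negative, second-darkest),
and their certain counterparts in the two lightest shades.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .phantom import CLASS_NAMES

DEFAULT_FLAG_THRESHOLD = 0.30

CERTAIN_NEGATIVE, CERTAIN_POSITIVE, UNCERTAIN_NEGATIVE, UNCERTAIN_POSITIVE = 0, 1, 2, 3
FLAG_NAMES = ("certain_negative", "certain_positive",
              "uncertain_negative", "uncertain_positive")
# 4-level sequential shades, darkest = uncertain_positive
_FLAG_SHADES = ("#f7f7f7", "#cccccc", "#636363", "#252525")


@dataclass
class FlagMap:
    categories: np.ndarray  # (H, W) codes 0..3
    threshold: float
    class_id: int | None    # None = all-classes mode (total PE)

    def count(self, code: int) -> int:
        return int((self.categories == code).sum())


def flag_pixels(
    label_mask: np.ndarray,
    per_class_pe: np.ndarray,
    threshold: float = DEFAULT_FLAG_THRESHOLD,
    class_id: int | None = 1,
) -> FlagMap:
    """Categorize pixels by predicted membership and PE above/below threshold.

    In per-class mode (default) "positive" means predicted as ``class_id``
    and the PE is that class's term; in all-classes mode (``class_id=None``)
    "positive" means predicted as any structure and the PE is the total
    predictive entropy (sum over classes).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    label_mask = np.asarray(label_mask)
    if class_id is None:
        positive = label_mask > 0
        pe = np.asarray(per_class_pe).sum(axis=0) if per_class_pe.ndim == 3 \
            else np.asarray(per_class_pe)
    else:
        positive = label_mask == class_id
        pe = np.asarray(per_class_pe)[class_id]
    if pe.shape != label_mask.shape:
        raise ValueError("PE map must align with the label mask")
    uncertain = pe > threshold
    categories = (positive.astype(np.uint8)
                  + 2 * uncertain.astype(np.uint8))
    return FlagMap(categories=categories, threshold=float(threshold), class_id=class_id)


def render_panels(
    image: np.ndarray,
    truth: np.ndarray,
    pred: np.ndarray,
    pe_map: np.ndarray,
    flag_map: FlagMap,
    out_path,
    error_map: np.ndarray | None = None,
) -> None:
    """Write the six-panel review figure (input, truth, prediction, error,
    PE map, flags) as a deterministic PNG.

    The prediction-error panel is the difference between the binarized mean
    prediction and the ground truth (0 where they agree).
    """
    if error_map is None:
        error_map = (np.asarray(pred, dtype=np.int16)
                     - np.asarray(truth, dtype=np.int16))
    fig, axes = plt.subplots(2, 3, figsize=(10.5, 7))
    panels = [
        ("input", image, dict(cmap="gray", vmin=0, vmax=1)),
        ("ground truth", truth, dict(cmap="viridis", vmin=0, vmax=3)),
        ("prediction", pred, dict(cmap="viridis", vmin=0, vmax=3)),
        ("prediction error", error_map, dict(cmap="coolwarm", vmin=-3, vmax=3)),
        ("predictive entropy (nats)", pe_map, dict(cmap="magma", vmin=0)),
        (f"flags (PE > {flag_map.threshold:g})", None, {}),
    ]
    for ax, (title, data, kw) in zip(axes.ravel(), panels):
        if data is not None:
            im = ax.imshow(data, interpolation="nearest", **kw)
            fig.colorbar(im, ax=ax, fraction=0.046)
        else:
            cmap = matplotlib.colors.ListedColormap(_FLAG_SHADES)
            im = ax.imshow(flag_map.categories, cmap=cmap, vmin=-0.5, vmax=3.5,
                           interpolation="nearest")
            cbar = fig.colorbar(im, ax=ax, fraction=0.046, ticks=range(4))
            cbar.ax.set_yticklabels(FLAG_NAMES, fontsize=6)
        ax.set_title(title, fontsize=9)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out_path, dpi=110, metadata={"Date": None, "Software": None})
    plt.close(fig)


def save_preview_png(image: np.ndarray, out_path) -> None:
    """Single-slice grayscale preview."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image, cmap="gray", vmin=0, vmax=1, interpolation="nearest")
    ax.axis("off")
    fig.savefig(out_path, dpi=110, bbox_inches="tight",
                metadata={"Date": None, "Software": None})
    plt.close(fig)
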