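"""Overlap and surface-distance metrics for binary segmentation masks.

Dice = 2|A n B| / (|A| + |B|).  Surface distances are computed between the
boundary point sets of the two masks: the boundary of a mask is the set of
its pixels with at least one non-mask 4-neighbour (edge pixels of the array
count as boundary).  The symmetric pool gathers, for every boundary point of
either mask, the distance to the nearest boundary point of the other mask;
HD95 is the 95th percentile of that pool (linear interpolation between order
statistics) and MSD its mean.  Anisotropic pixel spacing enters as physical
coordinates before the nearest-neighbour search, so both metrics scale
linearly with spacing.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Set-based Dice overlap; nan (undefined) when both masks are empty."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("masks must have the same shape")
    total = int(pred.sum()) + int(truth.sum())
    if total == 0:
        return float("nan")
    return 2.0 * int((pred & truth).sum()) / total


def boundary_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical coordinates of mask pixels with a non-mask face-neighbour
    (4-connectivity in 2D, 6-connectivity in 3D)."""
    mask = np.asarray(mask, dtype=bool)
    structure = generate_binary_structure(mask.ndim, 1)
    interior = binary_erosion(mask, structure=structure, border_value=0)
    boundary = mask & ~interior
    idx = np.argwhere(boundary)
    return idx * np.asarray(spacing, dtype=float)


def surface_distances(
    pred: np.ndarray, truth: np.ndarray, spacing=(1.0, 1.0)
) -> tuple[float, float]:
    """(hd95, msd) between two non-empty masks under the given pixel spacing."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("masks must have the same shape")
    if not pred.any() or not truth.any():
        raise ValueError("surface distances are undefined for an empty mask")
    if len(spacing) != pred.ndim:
        raise ValueError("spacing must give one length per axis")
    bp = boundary_points(pred, spacing)
    bt = boundary_points(truth, spacing)
    d_pred_to_truth = cKDTree(bt).query(bp)[0]
    d_truth_to_pred = cKDTree(bp).query(bt)[0]
    pool = np.concatenate([d_pred_to_truth, d_truth_to_pred])
    return float(np.percentile(pool, 95)), float(pool.mean())


def segmentation_report(
    pred_mask: np.ndarray,
    truth_mask: np.ndarray,
    spacing=(1.0, 1.0),
    class_ids=(1, 2, 3),
    class_names=("ctv", "bladder", "rectum"),
) -> dict[str, dict[str, float]]:
    """Per-structure DSC / HD95 / MSD for a pair of multi-class label masks.

    Distances are nan when either structure is absent from its mask (they are
    undefined, not zero).
    """
    report = {}
    for cid, name in zip(class_ids, class_names):
        p, t = pred_mask == cid, truth_mask == cid
        entry = {"dsc": dice(p, t)}
        if p.any() and t.any():
            entry["hd95"], entry["msd"] = surface_distances(p, t, spacing)
        else:
            entry["hd95"] = entry["msd"] = float("nan")
        report[name] = entry
    return report
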