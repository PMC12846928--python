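"""Pixel-outcome stratification and uncertainty-thresholded group Dice.

For each class c a pixel is TP (truth==c and pred==c), TN (both != c), FP
(pred==c only) or FN (truth==c only).  Per-class predictive entropy splits
the pixels of each class into a *certain* group (PE <= threshold) and an
*uncertain* group (PE strictly above), and each group's Dice is computed from
its TP/FP/FN counts as 2TP / (2TP + FP + FN); TN pixels enter neither
numerator nor denominator.  If uncertainty tracks correctness, the certain
group's Dice stays high while the uncertain group's collapses as the
threshold rises — the basis for flagging likely segmentation errors.

The default threshold sweep is 0.30 to 0.36 in steps of 0.01, bracketing the
analytic per-class PE maximum of 1/e ~ 0.368.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import CLASS_NAMES, N_CLASSES
from .uncertainty import MAX_PER_CLASS_PE

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.30, 0.361, 0.01), 2))

TP, TN, FP, FN = 0, 1, 2, 3
OUTCOME_NAMES = ("TP", "TN", "FP", "FN")


@dataclass
class OutcomeMap:
    """Per-class, per-pixel outcome codes, shape (C, H, W), values TP/TN/FP/FN."""

    codes: np.ndarray

    def mask(self, cls: int, outcome: int) -> np.ndarray:
        return self.codes[cls] == outcome

    def counts(self, cls: int) -> dict[str, int]:
        return {name: int((self.codes[cls] == code).sum())
                for code, name in enumerate(OUTCOME_NAMES)}


def classify_outcomes(pred: np.ndarray, truth: np.ndarray) -> OutcomeMap:
    """Stratify every pixel into TP/TN/FP/FN for each of the four classes."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have the same shape")
    for name, m in (("pred", pred), ("truth", truth)):
        if m.min() < 0 or m.max() >= N_CLASSES:
            raise ValueError(f"{name} labels must lie in 0..{N_CLASSES - 1}")
    codes = np.empty((N_CLASSES,) + pred.shape, dtype=np.uint8)
    for c in range(N_CLASSES):
        t, p = truth == c, pred == c
        codes[c] = np.where(t & p, TP,
                   np.where(~t & ~p, TN,
                   np.where(~t & p, FP, FN)))
    return OutcomeMap(codes=codes)


def pe_distribution_by_outcome(
    outcomes: OutcomeMap,
    per_class_pe: np.ndarray,
    bins: np.ndarray | None = None,
) -> pd.DataFrame:
    """Histogram of per-class PE per outcome category, with summary fractions.

    Returns one row per (class, outcome) with the bin counts, the category
    size, the fraction of pixels with PE <= 0.05 and the fraction with
    PE > 0.10, plus an ``empty`` flag for categories with no pixels.
    """
    if bins is None:
        bins = np.array([0.0, 0.05, 0.10, 0.20, 0.30, MAX_PER_CLASS_PE + 1e-12])
    bins = np.asarray(bins, dtype=float)
    if per_class_pe.shape != outcomes.codes.shape:
        raise ValueError("per_class_pe must align with the outcome map")
    rows = []
    for c in range(N_CLASSES):
        for code, oname in enumerate(OUTCOME_NAMES):
            vals = per_class_pe[c][outcomes.codes[c] == code]
            hist, _ = np.histogram(vals, bins=bins)
            rows.append({
                "class": CLASS_NAMES[c],
                "outcome": oname,
                "n_pixels": int(vals.size),
                "empty": vals.size == 0,
                "frac_le_0.05": float((vals <= 0.05).mean()) if vals.size else np.nan,
                "frac_gt_0.10": float((vals > 0.10).mean()) if vals.size else np.nan,
                **{f"bin_{lo:.3f}_{hi:.3f}": int(n)
                   for lo, hi, n in zip(bins[:-1], bins[1:], hist)},
            })
    return pd.DataFrame(rows)


@dataclass
class GroupDice:
    """Count-based Dice of the certain / uncertain pixel groups for one class."""

    certain_dice: float        # nan when undefined (2TP+FP+FN == 0)
    uncertain_dice: float
    certain_counts: dict[str, int]
    uncertain_counts: dict[str, int]

    @property
    def certain_defined(self) -> bool:
        return not np.isnan(self.certain_dice)

    @property
    def uncertain_defined(self) -> bool:
        return not np.isnan(self.uncertain_dice)


def _dice_from_counts(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else float("nan")


def grouped_dice(
    outcomes: OutcomeMap, per_class_pe: np.ndarray, threshold: float
) -> dict[str, GroupDice]:
    """Split pixels by per-class PE > threshold and Dice each group per class.

    Equality with the threshold keeps a pixel in the certain group ("above"
    is read strictly).  TN pixels are counted for transparency but never
    enter a Dice.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = {}
    for c in range(N_CLASSES):
        uncertain = per_class_pe[c] > threshold
        counts = {}
        for grp, sel in (("certain", ~uncertain), ("uncertain", uncertain)):
            counts[grp] = {name: int((outcomes.codes[c][sel] == code).sum())
                           for code, name in enumerate(OUTCOME_NAMES)}
        out[CLASS_NAMES[c]] = GroupDice(
            certain_dice=_dice_from_counts(
                counts["certain"]["TP"], counts["certain"]["FP"], counts["certain"]["FN"]),
            uncertain_dice=_dice_from_counts(
                counts["uncertain"]["TP"], counts["uncertain"]["FP"], counts["uncertain"]["FN"]),
            certain_counts=counts["certain"],
            uncertain_counts=counts["uncertain"],
        )
    return out


@dataclass
class ThresholdSweepResult:
    """Certain/uncertain group Dice across thresholds.

    ``per_image`` holds one row per (image, threshold, class);
    ``summary`` aggregates per (threshold, class) with the cohort mean and
    standard deviation of the per-image Dice plus a pooled-count variant.
    """

    thresholds: tuple[float, ...]
    per_image: pd.DataFrame
    summary: pd.DataFrame


def threshold_sweep(
    cases: list[tuple[OutcomeMap, np.ndarray]],
    thresholds=DEFAULT_THRESHOLDS,
) -> ThresholdSweepResult:
    """Sweep PE thresholds over a cohort of (outcomes, per-class PE) cases.

    Reports per-image group Dice and, per threshold and class, the cohort
    mean +/- sd over images where the group is defined, alongside Dice from
    pixel counts pooled over the whole cohort.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])) or not thresholds:
        raise ValueError("thresholds must be a non-empty strictly increasing list")
    rows = []
    for img_idx, (outcomes, pcpe) in enumerate(cases):
        for thr in thresholds:
            gd = grouped_dice(outcomes, pcpe, thr)
            for cname, g in gd.items():
                rows.append({
                    "image": img_idx, "threshold": thr, "class": cname,
                    "certain_dice": g.certain_dice,
                    "uncertain_dice": g.uncertain_dice,
                    **{f"certain_{k}": v for k, v in g.certain_counts.items()},
                    **{f"uncertain_{k}": v for k, v in g.uncertain_counts.items()},
                })
    per_image = pd.DataFrame(rows)
    agg = per_image.groupby(["threshold", "class"], sort=False).agg(
        certain_dice_mean=("certain_dice", "mean"),
        certain_dice_sd=("certain_dice", "std"),
        uncertain_dice_mean=("uncertain_dice", "mean"),
        uncertain_dice_sd=("uncertain_dice", "std"),
        **{k: (k, "sum") for k in per_image.columns
           if k.startswith(("certain_", "uncertain_")) and k.endswith(tuple(OUTCOME_NAMES))},
    ).reset_index()
    agg["certain_dice_pooled"] = [
        _dice_from_counts(r.certain_TP, r.certain_FP, r.certain_FN)
        for r in agg.itertuples()]
    agg["uncertain_dice_pooled"] = [
        _dice_from_counts(r.uncertain_TP, r.uncertain_FP, r.uncertain_FN)
        for r in agg.itertuples()]
    return ThresholdSweepResult(thresholds=thresholds, per_image=per_image, summary=agg)
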