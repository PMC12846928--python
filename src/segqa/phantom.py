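"""Synthetic pelvic phantom cohorts and model-free prediction ensembles.

The study's MR data (T2 prostate scans, in-distribution; bSSFP volunteer
scans, out-of-distribution) are not public, so this module generates 2D
grayscale phantoms with the same four-class structure: background (0), a
CTV-like central ellipse (1), a bladder-like ellipse above it (2) and a
rectum-like ellipse below it (3).  The out-of-distribution cohort differs
from the in-distribution cohort on both axes the clinical OOD data did:
image contrast (the bladder/background intensity ordering is inverted,
emulating the bSSFP vs. T2 contrast change) and shape statistics (smaller
bladders, more variable rectums, emulating volunteers without the patients'
drinking schedule).

``simulate_ensemble`` additionally produces stochastic softmax ensembles
directly from a ground-truth mask — without any network — with independent
knobs for epistemic spread (inter-sample logit jitter, driving mutual
information) and aleatoric boundary softness (driving predictive entropy),
so that every downstream stage is testable without training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy import ndimage

N_CLASSES = 4
CLASS_NAMES = ("background", "ctv", "bladder", "rectum")
LOGIT_CLIP = 10.0


class Cohort(str, Enum):
    ID = "ID"
    OOD = "OOD"


class PlacementError(RuntimeError):
    """Raised when non-overlapping structures cannot be placed."""


@dataclass(frozen=True)
class ShapeParams:
    """Per-structure ellipse geometry: mean center (row, col) as a fraction of
    the image side, mean semi-axes as a fraction of the side, and the relative
    jitter applied per scan."""

    center: tuple[float, float]
    axes: tuple[float, float]
    center_jitter: float = 0.03
    axes_jitter: float = 0.10


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one phantom cohort.

    ``intensity_means`` are per-class gray values in [0, 1] ordered as
    (background, ctv, bladder, rectum).  ``shape_params`` maps each structure
    (classes 1..3) to its ellipse distribution.
    """

    image_size: int = 64
    class_count: int = N_CLASSES
    intensity_means: tuple[float, float, float, float] = (0.20, 0.60, 0.90, 0.40)
    noise_sigma: float = 0.05
    shape_params: dict[int, ShapeParams] = field(
        default_factory=lambda: dict(_ID_SHAPES)
    )
    cohort: Cohort = Cohort.ID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_count != N_CLASSES:
            raise ValueError(f"class_count must be {N_CLASSES}")
        if len(self.intensity_means) != N_CLASSES:
            raise ValueError("intensity_means must have one entry per class")
        if not all(0.0 <= m <= 1.0 for m in self.intensity_means):
            raise ValueError("intensity_means must lie in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if set(self.shape_params) != {1, 2, 3}:
            raise ValueError("shape_params must cover classes 1..3")


_ID_SHAPES = {
    1: ShapeParams(center=(0.58, 0.50), axes=(0.11, 0.14), center_jitter=0.015),  # ctv
    2: ShapeParams(center=(0.22, 0.50), axes=(0.14, 0.13), center_jitter=0.015),  # bladder
    3: ShapeParams(center=(0.84, 0.50), axes=(0.065, 0.09), center_jitter=0.015,
                   axes_jitter=0.12),
}

# OOD: bladder darker than background (contrast inversion), smaller bladder,
# wider rectum-size spread.
_OOD_SHAPES = {
    1: ShapeParams(center=(0.58, 0.50), axes=(0.11, 0.14), center_jitter=0.015),
    2: ShapeParams(center=(0.22, 0.50), axes=(0.095, 0.08), center_jitter=0.015),
    3: ShapeParams(center=(0.84, 0.50), axes=(0.07, 0.095), center_jitter=0.015,
                   axes_jitter=0.28),
}


def default_spec(cohort: Cohort | str = Cohort.ID, seed: int = 0, **overrides) -> PhantomSpec:
    """The study's default ID / OOD phantom conditions."""
    cohort = Cohort(cohort)
    if cohort is Cohort.ID:
        spec = PhantomSpec(cohort=Cohort.ID, seed=seed)
    else:
        spec = PhantomSpec(
            cohort=Cohort.OOD,
            intensity_means=(0.45, 0.65, 0.15, 0.30),
            shape_params=dict(_OOD_SHAPES),
            seed=seed,
        )
    return replace(spec, **overrides) if overrides else spec


def _draw_ellipse_params(spec: PhantomSpec, rng: np.random.Generator) -> dict[int, tuple]:
    """Sample per-structure (center_r, center_c, ax_r, ax_c) in pixels."""
    n = spec.image_size
    params = {}
    for cls, sp in spec.shape_params.items():
        cr = (sp.center[0] + rng.normal(0, sp.center_jitter)) * n
        cc = (sp.center[1] + rng.normal(0, sp.center_jitter)) * n
        ar = sp.axes[0] * n * float(np.exp(rng.normal(0, sp.axes_jitter)))
        ac = sp.axes[1] * n * float(np.exp(rng.normal(0, sp.axes_jitter)))
        params[cls] = (cr, cc, max(ar, 2.0), max(ac, 2.0))
    return params


def _rasterize(params: dict[int, tuple], n: int) -> np.ndarray:
    rr, cc = np.mgrid[0:n, 0:n]
    mask = np.zeros((n, n), dtype=np.uint8)
    for cls in (2, 3, 1):  # ctv last so it wins nothing: overlap is rejected anyway
        cr, c0, ar, ac = params[cls]
        inside = ((rr - cr) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0
        mask[inside] = cls
    return mask


def _masks_disjoint(params: dict[int, tuple], n: int) -> bool:
    rr, cc = np.mgrid[0:n, 0:n]
    total = np.zeros((n, n), dtype=np.int64)
    for cr, c0, ar, ac in params.values():
        total += (((rr - cr) / ar) ** 2 + ((cc - c0) / ac) ** 2 <= 1.0)
    return bool(total.max() <= 1)


_MAX_PLACEMENT_TRIES = 50
_MIN_AREA_FRACTION = 0.01
# slack when validating scan-level geometry so per-slice jitter rarely
# creates overlaps (slice-level placement still rejects the residual cases)
_SCAN_MARGIN_INFLATE = 1.04
_SCAN_MARGIN_PAD = 1.0


def _draw_valid_scan_params(spec: PhantomSpec, rng: np.random.Generator) -> dict[int, tuple]:
    """Scan-level ellipse parameters, rejected until the structures stay
    disjoint and large enough even under per-slice jitter."""
    n = spec.image_size
    min_area = _MIN_AREA_FRACTION * n * n
    for _ in range(_MAX_PLACEMENT_TRIES):
        params = _draw_ellipse_params(spec, rng)
        inflated = {
            cls: (cr, c0, ar * _SCAN_MARGIN_INFLATE + _SCAN_MARGIN_PAD,
                  ac * _SCAN_MARGIN_INFLATE + _SCAN_MARGIN_PAD)
            for cls, (cr, c0, ar, ac) in params.items()
        }
        if not _masks_disjoint(inflated, n):
            continue
        areas = np.bincount(_rasterize(params, n).ravel(), minlength=N_CLASSES)
        if np.all(areas[1:] >= min_area):
            return params
    raise PlacementError(
        f"could not draw valid scan geometry in {_MAX_PLACEMENT_TRIES} tries"
    )


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate one phantom slice.

    Returns ``(image, mask)`` with ``image`` float64 in [0, 1] and ``mask``
    uint8 in {0..3}.  The three structures are pairwise non-overlapping and
    each covers at least 1% of the image; identical spec+seed is bitwise
    reproducible.  Raises :class:`PlacementError` if non-overlapping placement
    fails after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    return _generate_phantom_rng(spec, rng)


def _generate_phantom_rng(
    spec: PhantomSpec,
    rng: np.random.Generator,
    scan_params: dict[int, tuple] | None = None,
    slice_jitter: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    n = spec.image_size
    min_area = _MIN_AREA_FRACTION * n * n
    for _ in range(_MAX_PLACEMENT_TRIES):
        if scan_params is None:
            params = _draw_ellipse_params(spec, rng)
        else:
            params = {
                cls: (
                    cr + rng.normal(0, slice_jitter),
                    c0 + rng.normal(0, slice_jitter),
                    ar * float(np.exp(rng.normal(0, 0.03))),
                    ac * float(np.exp(rng.normal(0, 0.03))),
                )
                for cls, (cr, c0, ar, ac) in scan_params.items()
            }
        if not _masks_disjoint(params, n):
            continue
        mask = _rasterize(params, n)
        areas = np.bincount(mask.ravel(), minlength=N_CLASSES)
        if np.all(areas[1:] >= min_area):
            break
    else:
        raise PlacementError(
            f"could not place 3 non-overlapping structures in {_MAX_PLACEMENT_TRIES} tries"
        )
    image = np.asarray(spec.intensity_means, dtype=np.float64)[mask]
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    return np.clip(image, 0.0, 1.0), mask


def generate_cohort(
    spec: PhantomSpec, n_scans: int, slices_per_scan: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Generate a cohort of pseudo-3D scans.

    Each scan is a ``(slices, H, W)`` stack sharing per-scan structure
    parameters with a small per-slice perturbation, mimicking through-plane
    anatomical coherence.  One named substream per scan is derived from the
    master seed so the cohort is reproducible independent of generation order.
    """
    if n_scans < 1 or slices_per_scan < 1:
        raise ValueError("n_scans and slices_per_scan must be >= 1")
    scans = []
    root = np.random.SeedSequence(spec.seed)
    for child in root.spawn(n_scans):
        rng = np.random.default_rng(child)
        scan_params = _draw_valid_scan_params(spec, rng)
        imgs, masks = [], []
        for _ in range(slices_per_scan):
            img, msk = _generate_phantom_rng(
                spec, rng, scan_params=scan_params, slice_jitter=1.0
            )
            imgs.append(img)
            masks.append(msk)
        scans.append((np.stack(imgs), np.stack(masks)))
    return scans


# ---------------------------------------------------------------------------
# Model-free ensemble simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnsembleSimSpec:
    """Stochastic-ensemble simulation parameters.

    ``sigma_epistemic`` is the scale of zero-mean per-sample logit jitter
    (inter-sample disagreement, hence mutual information); ``sigma_aleatoric``
    is the boundary-softening length in pixels (per-sample entropy near
    boundaries, hence predictive entropy at fixed mutual information).
    """

    ground_truth: np.ndarray
    T: int = 50
    sigma_epistemic: float = 0.5
    sigma_aleatoric: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        gt = np.asarray(self.ground_truth)
        if gt.ndim != 2 or gt.min() < 0 or gt.max() >= N_CLASSES:
            raise ValueError("ground_truth must be a 2D mask with labels in 0..3")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.sigma_epistemic < 0 or self.sigma_aleatoric < 0:
            raise ValueError("sigma parameters must be >= 0")


def signed_distance_logits(mask: np.ndarray, sigma_aleatoric: float) -> np.ndarray:
    """Per-class logits = clipped signed Euclidean distance into each class
    region, in units of ``sigma_aleatoric`` pixels.

    Positive inside the class, negative outside; clipped to +/-10 so softmax
    saturates smoothly and predictive entropy concentrates at boundaries.
    """
    C = N_CLASSES
    logits = np.empty((C,) + mask.shape, dtype=np.float64)
    for c in range(C):
        inside = mask == c
        if not inside.any():
            logits[c] = -LOGIT_CLIP
            continue
        d_in = ndimage.distance_transform_edt(inside)
        d_out = ndimage.distance_transform_edt(~inside)
        logits[c] = d_in - d_out
    sigma = max(sigma_aleatoric, 1e-8)
    return np.clip(logits / sigma, -LOGIT_CLIP, LOGIT_CLIP)


def _softmax(logits: np.ndarray, axis: int) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def simulate_ensemble(spec: EnsembleSimSpec):
    """Simulate a T-sample stochastic softmax ensemble from a ground-truth mask.

    Returns a :class:`segqa.inference.PredictionEnsemble`.  With
    ``sigma_epistemic == 0`` all samples are identical (mutual information is
    exactly zero); as ``sigma_aleatoric -> 0`` the samples approach one-hot
    ground truth away from structure boundaries.
    """
    from .inference import PredictionEnsemble

    mask = np.asarray(spec.ground_truth)
    rng = np.random.default_rng(spec.seed)
    base = signed_distance_logits(mask, spec.sigma_aleatoric)  # (C, H, W)
    samples = np.empty((spec.T,) + base.shape, dtype=np.float64)
    for t in range(spec.T):
        logits = base
        if spec.sigma_epistemic > 0:
            logits = logits + rng.normal(0, spec.sigma_epistemic, size=base.shape)
        samples[t] = _softmax(logits, axis=0)
    return PredictionEnsemble(
        samples=samples,
        class_names=CLASS_NAMES,
        provenance={
            "source": "simulate_ensemble",
            "T": spec.T,
            "sigma_epistemic": spec.sigma_epistemic,
            "sigma_aleatoric": spec.sigma_aleatoric,
            "seed": spec.seed,
        },
    )
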