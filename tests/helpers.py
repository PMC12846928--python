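"""Independent scalar-loop oracles used by the unit and acceptance suites.

These deliberately avoid the package's vectorized code paths: entropies are
evaluated term by term in pure Python loops, surface distances by exhaustive
all-pairs search, so they can serve as ground truth for the fast
implementations.
"""

from __future__ import annotations

import math

import numpy as np


def scalar_entropy(p) -> float:
    """-sum p ln p with 0 ln 0 := 0, evaluated term by term."""
    return -sum(pi * math.log(pi) for pi in p if pi > 0)


def oracle_uncertainty(samples: np.ndarray):
    """Per-pixel PE / MI / per-class PE of a (T, C, H, W) ensemble, computed
    with explicit Python loops."""
    T, C, H, W = samples.shape
    pe = np.zeros((H, W))
    mi = np.zeros((H, W))
    pcpe = np.zeros((C, H, W))
    for i in range(H):
        for j in range(W):
            pbar = [sum(samples[t, c, i, j] for t in range(T)) / T for c in range(C)]
            pe[i, j] = scalar_entropy(pbar)
            for c in range(C):
                pcpe[c, i, j] = (-pbar[c] * math.log(pbar[c])) if pbar[c] > 0 else 0.0
            ee = sum(scalar_entropy(samples[t, :, i, j]) for t in range(T)) / T
            mi[i, j] = max(pe[i, j] - ee, 0.0)
    return pe, mi, pcpe


def random_ensemble(rng: np.random.Generator, T: int = 10, size: int = 16,
                    C: int = 4) -> np.ndarray:
    """Random valid ensemble: per pixel and sample a Dirichlet draw."""
    alpha = rng.uniform(0.2, 3.0, size=C)
    flat = rng.dirichlet(alpha, size=T * size * size)
    return flat.reshape(T, size, size, C).transpose(0, 3, 1, 2)


def oracle_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Mask pixels with at least one non-mask 4-neighbour, by explicit loops."""
    H, W = mask.shape
    pts = []
    for i in range(H):
        for j in range(W):
            if not mask[i, j]:
                continue
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if not (0 <= ni < H and 0 <= nj < W) or not mask[ni, nj]:
                    pts.append((i, j))
                    break
    return pts


def oracle_surface_distances(pred: np.ndarray, truth: np.ndarray,
                             spacing=(1.0, 1.0)) -> tuple[float, float]:
    """Brute-force all-pairs symmetric surface distances (hd95, msd)."""
    bp = oracle_boundary(pred)
    bt = oracle_boundary(truth)
    sy, sx = spacing

    def mindist(p, pts):
        return min(math.hypot((p[0] - q[0]) * sy, (p[1] - q[1]) * sx) for q in pts)

    pool = [mindist(p, bt) for p in bp] + [mindist(q, bp) for q in bt]
    return float(np.percentile(pool, 95)), float(np.mean(pool))


def random_blob_mask(rng: np.random.Generator, size: int = 24) -> np.ndarray:
    """Random non-empty blobby mask (union of 1-3 rectangles/discs)."""
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(rng.integers(1, 4)):
        if rng.random() < 0.5:
            r0, c0 = rng.integers(0, size - 4, 2)
            h, w = rng.integers(2, 8, 2)
            mask[r0:r0 + h, c0:c0 + w] = True
        else:
            cy, cx = rng.integers(3, size - 3, 2)
            rad = rng.integers(2, 6)
            yy, xx = np.ogrid[:size, :size]
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
    if not mask.any():
        mask[size // 2, size // 2] = True
    return mask
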