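"""Scan-level out-of-distribution scoring from global mean uncertainty.

A model applied outside the distribution it was trained on shows elevated
epistemic uncertainty, so the mean mutual information over all voxels of a
scan — no body masking, every voxel counts — is used as a one-number OOD
score.  Separation between an in-distribution and an out-of-distribution
cohort is assessed by an exhaustive scan over decision thresholds (a scan
is called OOD when its score is >= the threshold); 100% separation holds
iff max(ID) < min(OOD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ScanUncertaintySummary:
    scan_id: str
    mean_mi: float
    mean_pe: float
    cohort_label: str = "unknown"  # ID / OOD / unknown

    def __post_init__(self) -> None:
        ln4 = float(np.log(4.0))
        if not (0.0 <= self.mean_mi <= self.mean_pe + 1e-9 <= ln4 + 1e-9):
            raise ValueError("need 0 <= mean_mi <= mean_pe <= ln 4")


def summarize_scan(mi_volume: np.ndarray, pe_volume: np.ndarray,
                   scan_id: str, cohort_label: str = "unknown") -> ScanUncertaintySummary:
    """Arithmetic mean of the MI and PE maps over every voxel of a scan."""
    mi = np.asarray(mi_volume, dtype=float)
    pe = np.asarray(pe_volume, dtype=float)
    if mi.size == 0 or pe.size == 0:
        raise ValueError("cannot summarize an empty volume")
    if mi.shape != pe.shape:
        raise ValueError("MI and PE volumes must align")
    return ScanUncertaintySummary(scan_id=scan_id, mean_mi=float(mi.mean()),
                                  mean_pe=float(pe.mean()), cohort_label=cohort_label)


@dataclass
class SeparationReport:
    id_scores: list[float]
    ood_scores: list[float]
    best_accuracy: float
    threshold_interval: tuple[float, float]  # (lo, hi]: any threshold in it is optimal
    margin: float                            # min(OOD) - max(ID); > 0 iff 100% separation

    @property
    def fully_separated(self) -> bool:
        return self.margin > 0


def separation_analysis(id_summaries, ood_summaries,
                        score=lambda s: s.mean_mi) -> SeparationReport:
    """Best single-threshold accuracy for labelling scans OOD by their score.

    Every pooled score value is tried as a threshold (classification changes
    only there); the reported interval (lo, hi] is the contiguous range of
    thresholds achieving the best accuracy around its largest optimum.
    """
    if not id_summaries or not ood_summaries:
        raise ValueError("both cohorts must be non-empty")
    id_scores = [float(score(s)) for s in id_summaries]
    ood_scores = [float(score(s)) for s in ood_summaries]
    ids = np.asarray(id_scores)
    oods = np.asarray(ood_scores)
    n = ids.size + oods.size

    candidates = np.unique(np.concatenate([ids, oods, [np.inf]]))
    accuracies = np.array([
        ((ids < thr).sum() + (oods >= thr).sum()) / n for thr in candidates
    ])
    best = float(accuracies.max())
    best_idx = int(np.flatnonzero(accuracies == best)[-1])
    hi = float(candidates[best_idx])
    lo = float(candidates[best_idx - 1]) if best_idx > 0 else float("-inf")
    return SeparationReport(
        id_scores=id_scores,
        ood_scores=ood_scores,
        best_accuracy=best,
        threshold_interval=(lo, hi),
        margin=float(oods.min() - ids.max()),
    )
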