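"""Pixel-wise uncertainty measures from a Monte Carlo prediction ensemble.

Predictive entropy (PE) is the entropy of the sample-averaged class
distribution,

    H_hat = - sum_c p_bar_c ln p_bar_c,     p_bar_c = (1/T) sum_t p_{c,t},

and captures total (epistemic + aleatoric) uncertainty.  Mutual information
(MI) between the prediction and the dropout posterior over weights is the
predictive entropy minus the expected per-sample entropy,

    I_hat = H_hat + (1/T) sum_{c,t} p_{c,t} ln p_{c,t},

and isolates the epistemic part: it vanishes when the T samples agree.  The
per-class PE term -p_bar_c ln p_bar_c (the class-c summand of H_hat) is the
quantity thresholded in the error analysis; its analytic maximum is
1/e ~ 0.368 at p_bar_c = 1/e.

All entropies are in nats; the 0 * ln 0 := 0 convention is implemented by
masked evaluation, not an additive epsilon, so degenerate cases are exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inference import PredictionEnsemble

MAX_PER_CLASS_PE = float(np.exp(-1.0))  # 1/e, maximum of -p ln p

_MI_CLIP_TOL = 1e-9  # |negative MI| beyond this indicates a bug, not round-off


def _xlogx(p: np.ndarray) -> np.ndarray:
    """p * ln p with 0 ln 0 := 0, evaluated only where p > 0."""
    out = np.zeros_like(p)
    pos = p > 0
    out[pos] = p[pos] * np.log(p[pos])
    return out


def per_class_pe(ensemble: PredictionEnsemble) -> np.ndarray:
    """Per-class predictive-entropy terms -p_bar_c ln p_bar_c, shape (C, H, W)."""
    return -_xlogx(ensemble.mean_probs)


def predictive_entropy(ensemble: PredictionEnsemble) -> np.ndarray:
    """Predictive entropy H_hat per pixel (nats), shape (H, W)."""
    return per_class_pe(ensemble).sum(axis=0)


def expected_entropy(ensemble: PredictionEnsemble) -> np.ndarray:
    """Mean per-sample entropy E_t[-sum_c p_{c,t} ln p_{c,t}] per pixel."""
    return -_xlogx(ensemble.samples).sum(axis=1).mean(axis=0)


def _samples_identical(samples: np.ndarray) -> bool:
    return samples.shape[0] == 1 or bool(np.all(samples == samples[0]))


def mutual_information(ensemble: PredictionEnsemble) -> np.ndarray:
    """Mutual information I_hat per pixel (nats), clipped at 0 from below.

    When the T samples are identical (no inter-sample variation) MI is
    returned as exactly zero rather than via the cancelling subtraction.
    Floating-point cancellation can otherwise push MI a hair below zero;
    magnitudes beyond 1e-9 are treated as an implementation error.
    """
    if _samples_identical(ensemble.samples):
        return np.zeros(ensemble.samples.shape[2:])
    mi = predictive_entropy(ensemble) - expected_entropy(ensemble)
    neg = mi.min()
    if neg < -_MI_CLIP_TOL:
        raise FloatingPointError(f"MI fell below -{_MI_CLIP_TOL}: {neg}")
    return np.clip(mi, 0.0, None)


@dataclass
class UncertaintyMaps:
    """All uncertainty maps of one ensemble (nats)."""

    pe: np.ndarray              # (H, W) predictive entropy
    mi: np.ndarray              # (H, W) mutual information
    expected_entropy: np.ndarray  # (H, W)
    per_class_pe: np.ndarray    # (C, H, W)


def uncertainty_maps(ensemble: PredictionEnsemble) -> UncertaintyMaps:
    pcpe = per_class_pe(ensemble)
    pe = pcpe.sum(axis=0)
    ee = expected_entropy(ensemble)
    if _samples_identical(ensemble.samples):
        mi = np.zeros_like(pe)
    else:
        mi = pe - ee
        if mi.min() < -_MI_CLIP_TOL:
            raise FloatingPointError("MI fell below the round-off floor")
        mi = np.clip(mi, 0.0, None)
    return UncertaintyMaps(pe=pe, mi=mi, expected_entropy=ee, per_class_pe=pcpe)
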