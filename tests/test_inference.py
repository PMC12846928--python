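import inspect

import numpy as np
import pytest

from segqa.inference import (
    DEFAULT_T,
    PredictionEnsemble,
    mean_and_binarize,
    sample_ensemble,
    sample_ensemble_volume,
)
from segqa.phantom import Cohort, EnsembleSimSpec, default_spec, generate_phantom, simulate_ensemble


def _pixel_ensemble(*samples):
    arr = np.array(samples, dtype=float).reshape(len(samples), 4, 1, 1)
    return PredictionEnsemble(samples=arr)


class TestMeanAndBinarize:
    def test_strict_argmax(self):
        mp = mean_and_binarize(_pixel_ensemble([0.4, 0.3, 0.2, 0.1]))
        assert mp.label_mask[0, 0] == 0

    def test_all_way_tie_goes_to_background(self):
        mp = mean_and_binarize(_pixel_ensemble([0.25, 0.25, 0.25, 0.25]))
        assert mp.label_mask[0, 0] == 0

    def test_two_sample_tie_breaks_to_lowest_index(self):
        mp = mean_and_binarize(_pixel_ensemble([1, 0, 0, 0], [0, 0, 1, 0]))
        assert np.allclose(mp.mean_probs[:, 0, 0], [0.5, 0, 0.5, 0])
        assert mp.label_mask[0, 0] == 0

    def test_mean_stays_normalized(self, rng):
        from helpers import random_ensemble

        ens = PredictionEnsemble(samples=random_ensemble(rng, T=7, size=8))
        mp = mean_and_binarize(ens)
        assert np.abs(mp.mean_probs.sum(axis=0) - 1.0).max() < 1e-12
        assert np.array_equal(mp.mean_probs, ens.samples.mean(axis=0))


class TestSampling:
    def test_default_pass_count_is_50(self):
        assert DEFAULT_T == 50
        assert inspect.signature(sample_ensemble).parameters["T"].default == 50

    def test_single_sample_mean_equals_sample(self, tiny_trained):
        model, _, cohort = tiny_trained
        img = cohort[0][0][0]
        ens = sample_ensemble(model, img, T=1, seed=0)
        assert ens.T == 1
        assert np.array_equal(mean_and_binarize(ens).mean_probs, ens.samples[0])

    def test_seed_reproducibility(self, tiny_trained):
        model, _, cohort = tiny_trained
        img = cohort[0][0][0]
        e1 = sample_ensemble(model, img, T=4, seed=11)
        e2 = sample_ensemble(model, img, T=4, seed=11)
        assert np.array_equal(e1.samples, e2.samples)
        e3 = sample_ensemble(model, img, T=4, seed=12)
        assert not np.array_equal(e1.samples, e3.samples)

    def test_dropout_makes_samples_differ(self, tiny_trained):
        model, _, cohort = tiny_trained
        ens = sample_ensemble(model, cohort[0][0][0], T=4, seed=0)
        assert not np.array_equal(ens.samples[0], ens.samples[1])

    def test_volume_sampling_shapes(self, tiny_trained):
        model, _, cohort = tiny_trained
        vol = cohort[0][0]
        ensembles = sample_ensemble_volume(model, vol, T=3, seed=1)
        assert len(ensembles) == vol.shape[0]
        assert all(e.samples.shape == (3, 4) + vol.shape[1:] for e in ensembles)

    def test_invalid_T_rejected(self, tiny_trained):
        model, _, cohort = tiny_trained
        with pytest.raises(ValueError):
            sample_ensemble(model, cohort[0][0][0], T=0)


def test_sharp_simulated_ensemble_binarizes_to_truth_interior():
    """With no noise and sharp boundaries, binarization recovers the mask."""
    from scipy import ndimage

    mask = generate_phantom(default_spec(Cohort.ID, seed=9))[1]
    ens = simulate_ensemble(EnsembleSimSpec(ground_truth=mask, T=2,
                                            sigma_aleatoric=1e-4,
                                            sigma_epistemic=0.0, seed=0))
    pred = mean_and_binarize(ens).label_mask
    interior = np.ones_like(mask, dtype=bool)
    for c in range(4):
        inside = mask == c
        d = ndimage.distance_transform_edt(inside) + ndimage.distance_transform_edt(~inside)
        interior &= d > 2
    assert np.array_equal(pred[interior], mask[interior])
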