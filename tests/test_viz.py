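import numpy as np
import pytest

from segqa.error_analysis import classify_outcomes, grouped_dice
from segqa.inference import PredictionEnsemble, mean_and_binarize
from segqa.phantom import Cohort, EnsembleSimSpec, default_spec, generate_phantom, simulate_ensemble
from segqa.uncertainty import MAX_PER_CLASS_PE, per_class_pe, predictive_entropy
from segqa.viz import (
    CERTAIN_NEGATIVE,
    CERTAIN_POSITIVE,
    UNCERTAIN_NEGATIVE,
    UNCERTAIN_POSITIVE,
    flag_pixels,
    render_panels,
)


class TestFlagPixels:
    def test_perfect_one_hot_ensemble_is_all_certain(self, phantom_pair):
        _, mask = phantom_pair
        onehot = np.zeros((1, 4) + mask.shape)
        for c in range(4):
            onehot[0, c][mask == c] = 1.0
        ens = PredictionEnsemble(samples=onehot)
        fmap = flag_pixels(mask, per_class_pe(ens), threshold=0.30, class_id=1)
        assert fmap.count(UNCERTAIN_POSITIVE) == 0
        assert fmap.count(UNCERTAIN_NEGATIVE) == 0
        assert fmap.count(CERTAIN_POSITIVE) == (mask == 1).sum()

    def test_high_pe_predicted_pixel_is_uncertain_positive(self):
        labels = np.array([[1]])
        pcpe = np.zeros((4, 1, 1))
        pcpe[1, 0, 0] = 0.35
        fmap = flag_pixels(labels, pcpe, threshold=0.30, class_id=1)
        assert fmap.categories[0, 0] == UNCERTAIN_POSITIVE

    def test_threshold_above_per_class_maximum_disables_flags(self, rng):
        labels = rng.integers(0, 4, size=(8, 8))
        pcpe = rng.uniform(0, MAX_PER_CLASS_PE, size=(4, 8, 8))
        fmap = flag_pixels(labels, pcpe, threshold=MAX_PER_CLASS_PE + 0.01, class_id=2)
        assert fmap.count(UNCERTAIN_POSITIVE) == fmap.count(UNCERTAIN_NEGATIVE) == 0

    def test_categories_partition_pixels(self, rng):
        labels = rng.integers(0, 4, size=(10, 10))
        pcpe = rng.uniform(0, MAX_PER_CLASS_PE, size=(4, 10, 10))
        fmap = flag_pixels(labels, pcpe, threshold=0.2, class_id=3)
        total = sum(fmap.count(c) for c in
                    (CERTAIN_NEGATIVE, CERTAIN_POSITIVE,
                     UNCERTAIN_NEGATIVE, UNCERTAIN_POSITIVE))
        assert total == labels.size

    def test_flag_counts_reconcile_with_group_counts(self, rng):
        """Uncertain flags at a threshold match the uncertain-group size of
        the error analysis at the same threshold."""
        truth = rng.integers(0, 4, size=(12, 12))
        pred = rng.integers(0, 4, size=(12, 12))
        pcpe = rng.uniform(0, MAX_PER_CLASS_PE, size=(4, 12, 12))
        thr, cls = 0.22, 1
        fmap = flag_pixels(pred, pcpe, threshold=thr, class_id=cls)
        gd = grouped_dice(classify_outcomes(pred, truth), pcpe, thr)["ctv"]
        n_uncertain = fmap.count(UNCERTAIN_POSITIVE) + fmap.count(UNCERTAIN_NEGATIVE)
        assert n_uncertain == sum(gd.uncertain_counts.values())


@pytest.fixture(scope="module")
def case():
    image, mask = generate_phantom(default_spec(Cohort.ID, seed=6))
    ens = simulate_ensemble(EnsembleSimSpec(ground_truth=mask, T=10,
                                            sigma_epistemic=0.8, seed=1))
    pred = mean_and_binarize(ens).label_mask
    return image, mask, pred, ens


class TestRenderPanels:

    def test_rendering_is_deterministic(self, case, tmp_path):
        image, mask, pred, ens = case
        pe = predictive_entropy(ens)
        fmap = flag_pixels(pred, per_class_pe(ens), class_id=None)
        p1, p2 = tmp_path / "a.png", tmp_path / "b.png"
        render_panels(image, mask, pred, pe, fmap, p1)
        render_panels(image, mask, pred, pe, fmap, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_pe_peaks_on_structure_boundaries(self, case):
        """The hottest PE pixels of a boundary-noise ensemble lie within 2 px
        of a structure boundary."""
        from scipy import ndimage

        _, mask, _, ens = case
        pe = predictive_entropy(ens)
        near_boundary = np.zeros_like(mask, dtype=bool)
        for c in range(4):
            inside = mask == c
            if not inside.any():
                continue
            d = (ndimage.distance_transform_edt(inside)
                 + ndimage.distance_transform_edt(~inside))
            near_boundary |= d <= 2
        hottest = np.unravel_index(np.argmax(pe), pe.shape)
        assert near_boundary[hottest]

    def test_identical_truth_and_pred_give_empty_error_panel(self, case, tmp_path):
        image, mask, _, ens = case
        pe = predictive_entropy(ens)
        fmap = flag_pixels(mask, per_class_pe(ens), class_id=None)
        out = tmp_path / "c.png"
        render_panels(image, mask, mask, pe, fmap, out)
        assert out.exists() and out.stat().st_size > 0
        err = np.asarray(mask, dtype=np.int16) - np.asarray(mask, dtype=np.int16)
        assert not err.any()
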