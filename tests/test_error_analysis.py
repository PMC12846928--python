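import numpy as np
import pytest

from segqa.error_analysis import (
    DEFAULT_THRESHOLDS,
    FN,
    FP,
    TN,
    TP,
    OutcomeMap,
    classify_outcomes,
    grouped_dice,
    pe_distribution_by_outcome,
    threshold_sweep,
)
from segqa.inference import mean_and_binarize
from segqa.metrics import dice
from segqa.phantom import Cohort, EnsembleSimSpec, default_spec, generate_phantom, simulate_ensemble
from segqa.uncertainty import MAX_PER_CLASS_PE, per_class_pe


class TestClassifyOutcomes:
    def test_hand_worked_example(self):
        truth = np.array([[1, 1, 2, 0]])
        pred = np.array([[1, 2, 2, 2]])
        out = classify_outcomes(pred, truth)
        assert out.codes[1].tolist() == [[TP, FN, TN, TN]]
        assert out.codes[2].tolist() == [[TN, FP, TP, FP]]

    def test_identical_masks_have_no_errors(self, phantom_pair):
        _, mask = phantom_pair
        out = classify_outcomes(mask, mask)
        for c in range(4):
            assert not np.any((out.codes[c] == FP) | (out.codes[c] == FN))

    def test_all_background(self):
        z = np.zeros((3, 3), dtype=np.uint8)
        out = classify_outcomes(z, z)
        assert np.all(out.codes[0] == TP)
        for c in (1, 2, 3):
            assert np.all(out.codes[c] == TN)

    def test_outcomes_partition_pixels(self, rng):
        truth = rng.integers(0, 4, size=(20, 20))
        pred = rng.integers(0, 4, size=(20, 20))
        out = classify_outcomes(pred, truth)
        for c in range(4):
            counts = out.counts(c)
            assert sum(counts.values()) == truth.size

    def test_shape_and_label_validation(self):
        with pytest.raises(ValueError):
            classify_outcomes(np.zeros((2, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            classify_outcomes(np.full((2, 2), 5), np.zeros((2, 2)))


class TestDistributions:
    def test_histogram_conserves_category_sizes(self, rng):
        truth = rng.integers(0, 4, size=(16, 16))
        pred = rng.integers(0, 4, size=(16, 16))
        out = classify_outcomes(pred, truth)
        pcpe = rng.uniform(0, MAX_PER_CLASS_PE, size=(4, 16, 16))
        table = pe_distribution_by_outcome(out, pcpe,
                                           bins=np.array([0, 0.05, 0.10, MAX_PER_CLASS_PE]))
        bins = [c for c in table.columns if c.startswith("bin_")]
        assert (table[bins].sum(axis=1) == table["n_pixels"]).all()
        assert table["n_pixels"].sum() == 4 * truth.size

    def test_confident_correct_prediction_fraction(self):
        truth = np.array([[1, 0], [0, 0]])
        out = classify_outcomes(truth, truth)
        pcpe = np.zeros((4, 2, 2))  # one-hot means: zero PE everywhere
        table = pe_distribution_by_outcome(out, pcpe)
        correct = table[table["outcome"].isin(["TP", "TN"])]
        assert (correct["frac_le_0.05"].dropna() == 1.0).all()

    def test_boundary_errors_have_higher_pe_than_correct_pixels(self):
        """On a simulated noisy ensemble, wrongly predicted pixels carry
        higher median per-class PE than correct ones."""
        mask = generate_phantom(default_spec(Cohort.ID, seed=12))[1]
        ens = simulate_ensemble(EnsembleSimSpec(ground_truth=mask, T=25,
                                                sigma_aleatoric=2.0,
                                                sigma_epistemic=1.0, seed=4))
        pred = mean_and_binarize(ens).label_mask
        out = classify_outcomes(pred, mask)
        pcpe = per_class_pe(ens)
        for c in (1, 2, 3):
            wrong = (out.codes[c] == FP) | (out.codes[c] == FN)
            correct = ~wrong
            if wrong.any():
                assert (np.median(pcpe[c][wrong]) > np.median(pcpe[c][correct]))


class TestGroupedDice:
    def _case(self):
        """6 class-1 pixels arranged to give TP=3, FP=1, FN=2, rest TN."""
        truth = np.array([[1, 1, 1, 1, 1, 0, 0, 0]])
        pred = np.array([[1, 1, 1, 0, 0, 1, 0, 0]])
        return classify_outcomes(pred, truth)

    def test_count_based_formula(self):
        out = self._case()
        pcpe = np.zeros((4, 1, 8))
        gd = grouped_dice(out, pcpe, threshold=0.3)
        assert gd["ctv"].certain_dice == pytest.approx(6 / 9)
        assert np.isnan(gd["ctv"].uncertain_dice)  # empty group: undefined

    def test_perfect_prediction(self, phantom_pair):
        _, mask = phantom_pair
        out = classify_outcomes(mask, mask)
        pcpe = np.zeros((4,) + mask.shape)
        gd = grouped_dice(out, pcpe, threshold=0.1)
        for g in gd.values():
            assert g.certain_dice == 1.0 or np.isnan(g.certain_dice)
            assert g.uncertain_counts["FP"] == g.uncertain_counts["FN"] == 0

    def test_zero_threshold_with_positive_pe_empties_certain_group(self):
        out = self._case()
        pcpe = np.full((4, 1, 8), 0.2)
        gd = grouped_dice(out, pcpe, threshold=0.0)
        assert np.isnan(gd["ctv"].certain_dice)
        assert gd["ctv"].uncertain_dice == pytest.approx(6 / 9)

    def test_equality_stays_certain(self):
        out = self._case()
        pcpe = np.full((4, 1, 8), 0.25)
        gd = grouped_dice(out, pcpe, threshold=0.25)
        assert gd["ctv"].certain_dice == pytest.approx(6 / 9)

    @pytest.mark.parametrize("seed", range(10))
    def test_above_max_threshold_equals_set_based_dice(self, seed):
        """At a threshold above the per-class PE maximum every pixel is
        certain and the count-based Dice equals the set-based Dice."""
        rng = np.random.default_rng(seed)
        truth = rng.integers(0, 4, size=(12, 12))
        pred = rng.integers(0, 4, size=(12, 12))
        out = classify_outcomes(pred, truth)
        pcpe = rng.uniform(0, MAX_PER_CLASS_PE, size=(4, 12, 12))
        gd = grouped_dice(out, pcpe, threshold=MAX_PER_CLASS_PE)
        from segqa.phantom import CLASS_NAMES

        for c, name in enumerate(CLASS_NAMES):
            expected = dice(pred == c, truth == c)
            got = gd[name].certain_dice
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=0)
            assert sum(gd[name].uncertain_counts.values()) == 0

    def test_group_counts_conserve_totals(self, rng):
        truth = rng.integers(0, 4, size=(15, 15))
        pred = rng.integers(0, 4, size=(15, 15))
        out = classify_outcomes(pred, truth)
        pcpe = rng.uniform(0, MAX_PER_CLASS_PE, size=(4, 15, 15))
        gd = grouped_dice(out, pcpe, threshold=0.2)
        for name, g in gd.items():
            total = {k: g.certain_counts[k] + g.uncertain_counts[k]
                     for k in g.certain_counts}
            assert sum(total.values()) == truth.size


class TestThresholdSweep:
    def test_default_thresholds(self):
        assert list(DEFAULT_THRESHOLDS) == [0.30, 0.31, 0.32, 0.33, 0.34, 0.35, 0.36]

    def test_sweep_tables_are_consistent(self, rng):
        cases = []
        for _ in range(3):
            truth = rng.integers(0, 4, size=(10, 10))
            pred = rng.integers(0, 4, size=(10, 10))
            cases.append((classify_outcomes(pred, truth),
                          rng.uniform(0, MAX_PER_CLASS_PE, size=(4, 10, 10))))
        res = threshold_sweep(cases, thresholds=[0.1, 0.2, 0.3])
        assert res.thresholds == (0.1, 0.2, 0.3)
        assert len(res.per_image) == 3 * 3 * 4
        # pooled counts at each threshold cover all pixels of all images
        for _, row in res.summary.iterrows():
            total = sum(row[f"certain_{k}"] + row[f"uncertain_{k}"]
                        for k in ("TP", "TN", "FP", "FN"))
            assert total == 3 * 100

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            threshold_sweep([], thresholds=[0.3, 0.2])
        with pytest.raises(ValueError):
            threshold_sweep([], thresholds=[])
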