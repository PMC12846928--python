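import math

import numpy as np
import pytest

from helpers import oracle_uncertainty, random_ensemble, scalar_entropy
from segqa.inference import PredictionEnsemble
from segqa.uncertainty import (
    MAX_PER_CLASS_PE,
    expected_entropy,
    mutual_information,
    per_class_pe,
    predictive_entropy,
    uncertainty_maps,
)


def _pixel_ensemble(*samples):
    """Build a 1x1-pixel ensemble from per-sample probability 4-vectors."""
    arr = np.array(samples, dtype=float).reshape(len(samples), 4, 1, 1)
    return PredictionEnsemble(samples=arr)


class TestAnalyticAnchors:
    def test_uniform_pixel_reaches_ln4(self):
        ens = _pixel_ensemble([0.25, 0.25, 0.25, 0.25])
        assert predictive_entropy(ens)[0, 0] == pytest.approx(math.log(4), abs=1e-12)

    def test_one_hot_pixel_has_zero_entropy(self):
        ens = _pixel_ensemble([1.0, 0.0, 0.0, 0.0])
        assert predictive_entropy(ens)[0, 0] == 0.0
        assert per_class_pe(ens)[:, 0, 0].tolist() == [0.0, 0.0, 0.0, 0.0]

    def test_hand_computed_entropy(self):
        ens = _pixel_ensemble([0.7, 0.1, 0.1, 0.1])
        assert predictive_entropy(ens)[0, 0] == pytest.approx(0.940448, abs=1e-6)

    def test_disagreeing_one_hot_samples_give_ln2_mi(self):
        ens = _pixel_ensemble([1, 0, 0, 0], [0, 1, 0, 0])
        assert mutual_information(ens)[0, 0] == pytest.approx(math.log(2), abs=1e-12)
        assert expected_entropy(ens)[0, 0] == 0.0

    def test_hand_computed_mi(self):
        ens = _pixel_ensemble([0.6, 0.4, 0, 0], [0.8, 0.2, 0, 0])
        assert mutual_information(ens)[0, 0] == pytest.approx(0.024157, abs=1e-6)

    def test_per_class_pe_maximum_at_1_over_e(self):
        p = math.exp(-1)
        ens = _pixel_ensemble([p, 1 - p, 0, 0])
        assert per_class_pe(ens)[0, 0, 0] == pytest.approx(MAX_PER_CLASS_PE, abs=1e-12)
        # 1/e is the analytic maximum of -p ln p
        grid = np.linspace(1e-6, 1 - 1e-6, 10001)
        assert np.max(-grid * np.log(grid)) <= MAX_PER_CLASS_PE + 1e-9

    def test_half_probability_term(self):
        ens = _pixel_ensemble([0.5, 0.5, 0, 0])
        assert per_class_pe(ens)[0, 0, 0] == pytest.approx(0.5 * math.log(2), abs=1e-12)

    def test_identical_samples_have_exactly_zero_mi(self):
        sample = [0.4, 0.3, 0.2, 0.1]
        ens = _pixel_ensemble(*([sample] * 7))
        assert mutual_information(ens)[0, 0] == 0.0


class TestAgainstScalarOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_vectorized_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        samples = random_ensemble(rng, T=10, size=16)
        ens = PredictionEnsemble(samples=samples)
        pe_o, mi_o, pcpe_o = oracle_uncertainty(samples)
        maps = uncertainty_maps(ens)
        assert np.abs(maps.pe - pe_o).max() < 1e-10
        assert np.abs(maps.mi - mi_o).max() < 1e-10
        assert np.abs(maps.per_class_pe - pcpe_o).max() < 1e-10

    @pytest.mark.parametrize("seed", range(20))
    def test_bounds_and_decomposition(self, seed):
        rng = np.random.default_rng(100 + seed)
        samples = random_ensemble(rng, T=6, size=8)
        maps = uncertainty_maps(PredictionEnsemble(samples=samples))
        assert maps.mi.min() >= 0.0
        assert np.all(maps.mi <= maps.pe + 1e-9)
        assert maps.pe.max() <= math.log(4) + 1e-9
        assert np.all(maps.per_class_pe >= 0.0)
        assert maps.per_class_pe.max() <= MAX_PER_CLASS_PE + 1e-12
        assert np.abs(maps.per_class_pe.sum(axis=0) - maps.pe).max() == 0.0


def test_invalid_ensembles_rejected():
    with pytest.raises(ValueError):
        PredictionEnsemble(samples=np.full((2, 4, 2, 2), 0.3))  # sums to 1.2
    with pytest.raises(ValueError):
        PredictionEnsemble(samples=np.ones((2, 3, 2, 2)) / 3)  # wrong class count
    with pytest.raises(ValueError):
        PredictionEnsemble(samples=np.zeros((0, 4, 2, 2)))  # T = 0


def test_scalar_entropy_helper_consistency():
    # the oracle itself must satisfy the closed forms it is trusted for
    assert scalar_entropy([0.25] * 4) == pytest.approx(math.log(4), abs=1e-12)
    assert scalar_entropy([1.0, 0, 0, 0]) == 0.0
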