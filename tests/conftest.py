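import numpy as np
import pytest

from segqa.model import ModelConfig, TrainConfig, build_model, train
from segqa.phantom import Cohort, default_spec, generate_cohort, generate_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom_pair():
    """One deterministic 64x64 phantom image/mask pair."""
    return generate_phantom(default_spec(Cohort.ID, seed=7))


@pytest.fixture(scope="session")
def tiny_trained():
    """A very small U-Net briefly trained on a 3-scan 32x32 cohort.

    Deliberately under-trained: enough for contracts (loss decreases,
    dropout probabilities learned, checkpoints round-trip), not accuracy.
    """
    cohort = generate_cohort(
        default_spec(Cohort.ID, seed=21, image_size=32), n_scans=3, slices_per_scan=2
    )
    model = build_model(ModelConfig(levels=2, base_channels=8), seed=3)
    result = train(model, cohort, TrainConfig(epochs=3, batch_size=4, seed=5))
    return model, result, cohort
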