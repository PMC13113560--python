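import numpy as np
import pytest

from cabif.pipeline import TrainConfig
from cabif.synthetic_data import SyntheticSpec, generate_multimodal_dataset


@pytest.fixture(scope="session")
def canonical_spec() -> SyntheticSpec:
    """The canonical synthetic benchmark: 20 classes, 64-dim embeddings,
    separation 3, unit noise, audio degraded x4 on half the samples."""
    return SyntheticSpec()


@pytest.fixture(scope="session")
def canonical_data(canonical_spec):
    """2,000 train / 400 test samples of the canonical benchmark (seed 0)."""
    train = generate_multimodal_dataset(canonical_spec, stream=0)
    test = generate_multimodal_dataset(canonical_spec, samples_per_class=20, stream=1)
    return train, test


@pytest.fixture(scope="session")
def canonical_config() -> TrainConfig:
    return TrainConfig(epochs=30, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
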