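import numpy as np
import pytest

from omicfuse import SyntheticSpec, TrainConfig, generate_multiomics


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def easy_dataset():
    """Small well-separated 3-subtype cohort used across trainer tests."""
    spec = SyntheticSpec(
        n_samples=120, n_omics=2, n_clusters=3, dims=(20, 30),
        separation=8.0, noise_sd=1.0, seed=7,
    )
    return generate_multiomics(spec)


@pytest.fixture
def quick_config():
    """Short schedule for trainer unit tests (not the study conditions)."""
    return TrainConfig(pretrain_epochs=40, finetune_epochs=20, d=8, seed=3)
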