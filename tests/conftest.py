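import numpy as np
import pytest

from motorpool import SimConfig, gen_series


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_config():
    """Distortion-free simulation config (identity geometry)."""
    return SimConfig(
        seed=7,
        n_sections=12,
        neurons_per_pool=40,
        enlargement_amplitude=0.0,
        rigid_jitter_translation=0.0,
        rigid_jitter_rotation=0.0,
        landmark_noise=0.0,
    )


@pytest.fixture
def clean_series(clean_config):
    return gen_series(clean_config, animal_seed=11, animal_id="clean")


@pytest.fixture
def distorted_config():
    """Enlargement + rigid jitter, no landmark noise."""
    return SimConfig(
        seed=7,
        n_sections=20,
        neurons_per_pool=50,
        enlargement_amplitude=0.3,
        enlargement_width=4.0,
        rigid_jitter_translation=0.05,
        rigid_jitter_rotation=0.05,
        landmark_noise=0.0,
    )
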