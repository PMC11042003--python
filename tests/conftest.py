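import numpy as np
import pytest

from odcup.model import ModelConfig
from odcup.synthetic import PhantomSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20240328)


@pytest.fixture
def desk_cfg():
    return ModelConfig.desk_scale(seed=1)


@pytest.fixture
def tiny_cfg():
    """Very small network for fast unit tests."""
    return ModelConfig(input_side=32, base_channels=4, depth=2, seed=3)


@pytest.fixture
def small_spec():
    return PhantomSpec(n_images=4, height_range=(72, 96), width_range=(72, 96),
                       seed=42)
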