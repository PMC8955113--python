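import numpy as np
import pytest

from thermofall.synthetic import SceneConfig


@pytest.fixture
def quiet_config() -> SceneConfig:
    """Noise-free scene: constant background, no pixel noise."""
    return SceneConfig(bg_drift_sigma=0.0, pixel_noise_sigma=0.0, seed=0)


@pytest.fixture
def default_config() -> SceneConfig:
    return SceneConfig(seed=0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
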