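import numpy as np
import pytest

import brainguard as bg


@pytest.fixture(scope="session")
def small_scene():
    """Desk-scale scene: enough points to resolve the probe region."""
    return bg.SceneConfig(n_points=800, rng_seed=3)


@pytest.fixture(scope="session")
def small_monitor_data(small_scene):
    """A reduced monitor-mode dataset pair for fast workflow tests."""
    return bg.generate_dataset(small_scene, "monitor", n=240, split=0.8, seed=5)


@pytest.fixture(scope="session")
def small_emulator(small_monitor_data):
    train, _ = small_monitor_data
    return bg.train_emulator(train, bg.TrainConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
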