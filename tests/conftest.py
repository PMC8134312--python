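import numpy as np
import pytest

from drillpose.fixtures import default_toy_assets
from drillpose.scene import GenerationConfig, generate_dataset


@pytest.fixture(scope="session")
def toy():
    """Toy drill assets + the seven authored grasp templates (cached)."""
    assets, templates = default_toy_assets()
    return assets, templates


@pytest.fixture(scope="session")
def small_dataset(toy):
    """A small generated dataset shared by the read-only tests."""
    assets, templates = toy
    samples, report = generate_dataset(
        assets, templates, GenerationConfig(n_samples=8), seed=11)
    return samples, report


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
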