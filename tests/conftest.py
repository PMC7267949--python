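import numpy as np
import pytest

from priorseg.phantoms import PhantomConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    """Smallest admissible grid, small structures: fast to generate and train on."""
    return PhantomConfig(grid_side=32, structure_radius=4.0, intersubject_alpha=2.0, seed=3)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config, 6)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
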