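import numpy as np
import pytest

from mycoroot.pipeline import run_pipeline
from mycoroot.synthetic_data import WorldConfig, generate_world


@pytest.fixture(scope="session")
def default_world():
    """A small world with all perturbations on (noise, gaps, flags)."""
    cfg = WorldConfig(
        grid_shape=(24, 24),
        species_pool_size=240,
        plots_per_unit=12,
        seed=11,
        categorical_class_bounds=((0.0, 25.0), (25.0, 50.0), (50.0, 100.0)),
        fraction_categorical=0.2,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def exact_world():
    """Zero observation noise, full coverage: truth is exactly recoverable."""
    cfg = WorldConfig(
        grid_shape=(24, 24),
        species_pool_size=240,
        plots_per_unit=12,
        seed=5,
        intensity_noise_sd=0.0,
        fraction_species_no_records=0.0,
        fraction_categorical=0.0,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def exact_result(exact_world):
    return run_pipeline(exact_world.inputs)


@pytest.fixture(scope="session")
def default_result(default_world):
    return run_pipeline(default_world.inputs)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
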