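import numpy as np
import pytest

from glymphflow import SimulationConfig, generate_aif


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def time_grid(default_config) -> np.ndarray:
    return default_config.time_grid


@pytest.fixture(scope="session")
def bolus_aif(default_config, time_grid):
    """The generator's default acquisition AIF (bolus-dominant)."""
    return generate_aif(time_grid, default_config.dose_mmol_per_kg,
                        default_config.aif_shape)


@pytest.fixture(scope="session")
def weinmann_aif(time_grid):
    """The literature population AIF (slow bi-exponential)."""
    return generate_aif(time_grid, 0.1)
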