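import numpy as np
import pytest

from hqscape import (LandscapeConfig, LandUseRaster, default_sensitivity,
                     generate_covariates, generate_landuse_series)


@pytest.fixture(scope="session")
def sens():
    return default_sensitivity()


@pytest.fixture(scope="session")
def small_config():
    return LandscapeConfig(
        grid_rows=64, grid_cols=64, cell_size=30.0, seed=11,
        forest_fraction_target=0.9, n_years=3,
        settlement_centers=[(48, 16)],
        transition_rates={(1, 2): 0.05, (2, 6): 0.10, (3, 1): 0.04},
    )


@pytest.fixture(scope="session")
def small_landscape(small_config):
    cov = generate_covariates(small_config)
    series, truth = generate_landuse_series(small_config, cov)
    return cov, series, truth


def random_landuse(seed: int, shape=(20, 20), cell_size=30.0) -> LandUseRaster:
    rng = np.random.default_rng(seed)
    return LandUseRaster(values=rng.integers(1, 8, shape), cell_size=cell_size)
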