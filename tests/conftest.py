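import warnings

import numpy as np
import pytest

from socgeo.dataset_io import LocationGrid
from socgeo.synthetic_data import (
    FieldParams,
    default_layer_params,
    simulate_layer,
)


@pytest.fixture(scope="session")
def survey_grid():
    """The full 5 km x 8 km / 500 m lattice (187 locations)."""
    return LocationGrid()


@pytest.fixture(scope="session")
def small_grid():
    """A 1 km x 1 km / 500 m lattice (9 locations) for fast tests."""
    return LocationGrid(1000.0, 1000.0, 500.0)


@pytest.fixture(scope="session")
def surface_params():
    """Survey-calibrated surface-layer generating parameters."""
    return default_layer_params("0-10")


@pytest.fixture(scope="session")
def surface_layer(survey_grid, surface_params):
    """One deterministic simulated surface layer on the full grid."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # covariate clipping is expected
        return simulate_layer(survey_grid, surface_params, "0-10", seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def plain_field_params():
    """Surface-layer SOC parameters without covariates (fast generation)."""
    return FieldParams(mean=1.6, cv=0.368, nugget_ratio=0.0019 / 0.1048,
                      range_m=1347.0)
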