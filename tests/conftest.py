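import numpy as np
import pytest

from mdfps import apply_indicator, make_admin_grid
from mdfps.geometry import GridSpec
from mdfps.synthetic import GroundTruth, simulate_covariate_rasters, simulate_survey


@pytest.fixture(scope="session")
def admin9():
    return make_admin_grid(9, 90.0)


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(0.0, 0.0, 5.0, 18, 18)


@pytest.fixture(scope="session")
def small_stack(small_grid):
    return simulate_covariate_rasters(small_grid, seed=11)


@pytest.fixture(scope="session")
def multilevel_survey(admin9, small_stack):
    """Medium survey with nested random effects and a known rural deficit."""
    truth = GroundTruth(
        beta={"intercept": 0.3, "residence=rural": np.log(0.6)},
        sigma_region=0.5,
        sigma_cluster=0.5,
        seed=101,
    )
    return simulate_survey(
        truth, admin9, small_stack, n_clusters=60, n_women_per_cluster=20,
        mechanism="multilevel", seed=7,
    )


@pytest.fixture(scope="session")
def multilevel_indicator(multilevel_survey):
    res, _ = apply_indicator(multilevel_survey.women)
    return res
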