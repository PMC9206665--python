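import numpy as np
import pytest
from hypothesis import settings

from topwet.core import CTISubgrid
from topwet.synthetic import (
    SynthConfig,
    gen_cti_field,
    gen_forcing,
    gen_true_m,
    gen_truth_obs,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def random_subgrid(rng, n_pixels=2500, total_area=600.0, gap=0.0):
    """Right-skewed CTI subgrid with equal pixel areas."""
    cti = 2.0 + rng.gamma(3.0, 1.5, n_pixels)
    pixel_area = total_area * (1.0 - gap) / n_pixels
    return CTISubgrid(
        row=0, col=0, cti=cti,
        areas=np.full(n_pixels, pixel_area), total_area=total_area,
    )


@pytest.fixture(scope="session")
def subgrid():
    return random_subgrid(np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(seed=11, n_lat=4, n_lon=4, n_months=36, pixels_per_cell=600)


@pytest.fixture(scope="session")
def small_world(small_config):
    """CTI grid, forcing, hidden truth and its forward observations."""
    cti = gen_cti_field(small_config)
    forcing = gen_forcing(small_config)
    true_m = gen_true_m(small_config)
    monthly, obs_max = gen_truth_obs(cti, forcing, true_m)
    return dict(
        config=small_config, cti=cti, forcing=forcing,
        true_m=true_m, obs_monthly=monthly, obs_max=obs_max,
    )


@pytest.fixture(scope="session")
def recovery_world():
    """The 10x10-cell recovery experiment world (hidden M per cell)."""
    config = SynthConfig(seed=42)
    cti = gen_cti_field(config)
    forcing = gen_forcing(config)
    true_m = gen_true_m(config)
    monthly, obs_max = gen_truth_obs(cti, forcing, true_m)
    return dict(
        config=config, cti=cti, forcing=forcing,
        true_m=true_m, obs_monthly=monthly, obs_max=obs_max,
    )
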