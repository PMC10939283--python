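import numpy as np
import pytest

from crowdcontacts import ForceParams, fixture_location_configs
from crowdcontacts.population import GaussianSpec, LocationConfig, PROXEMIC_ZONES, N_AGE_BINS


@pytest.fixture(scope="session")
def configs():
    return fixture_location_configs()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_degenerate_config(
    name="workplace",
    zone="personal",
    speed=1.2,
    distance=None,
    mass=70.0,
    bin_index=4,
    force=None,
):
    """Single-age-bin, zero-variance location config for exact tests."""
    z = PROXEMIC_ZONES[zone]
    if distance is None:
        distance = 0.5 * (z.range_lo + z.range_hi)
    weights = [0.0] * N_AGE_BINS
    weights[bin_index] = 1.0
    return LocationConfig(
        name=name,
        zone=z,
        duration_h=8.0,
        demographic_weights=tuple(weights),
        speed_dist=tuple(GaussianSpec(speed, 0.0) for _ in range(N_AGE_BINS)),
        distance_dist=tuple(GaussianSpec(distance, 0.0) for _ in range(N_AGE_BINS)),
        mass_dist=GaussianSpec(mass, 0.0),
        force=force or ForceParams(),
    )


@pytest.fixture
def degenerate_config():
    return make_degenerate_config()
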