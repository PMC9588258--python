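import numpy as np
import pytest
from hypothesis import settings

from drgsqa import FixtureConfig, MachineLimits, make_epid_pair, make_vendor_replica_plan

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def truebeam_limits() -> MachineLimits:
    """Flattened-beam TrueBeam: 600 MU/min, 6 deg/s, 60 MU/deg ceiling."""
    return MachineLimits(max_dose_rate=600.0, max_gantry_speed=6.0, max_mu_per_deg=60.0)


@pytest.fixture(scope="session")
def vendor_plan():
    return make_vendor_replica_plan(FixtureConfig())


def small_epid_config(**overrides) -> FixtureConfig:
    """A small imager geometry so image-heavy tests stay fast."""
    defaults = dict(
        image_shape=(96, 128),
        strip_width_px=8,
        strip_pitch_px=16,
        field_rows=(20, 76),
    )
    defaults.update(overrides)
    return FixtureConfig(**defaults)


@pytest.fixture()
def small_config() -> FixtureConfig:
    return small_epid_config()


@pytest.fixture()
def noiseless_pair(small_config):
    return make_epid_pair(small_config)
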