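import numpy as np
import pytest

from esbundles import GridSpec, LandscapeConfig, generate_landscape, rasterize_hierarchy


@pytest.fixture(scope="session")
def small_config() -> LandscapeConfig:
    return LandscapeConfig(
        spec=GridSpec(60, 60), seed=7,
        n_counties=2, townships_per_county=2, villages_per_township=2,
    )


@pytest.fixture(scope="session")
def small_landscape(small_config):
    """60×60 stack with a 2/4/8 county/township/village hierarchy."""
    return generate_landscape(small_config)


@pytest.fixture(scope="session")
def small_zones(small_landscape):
    stack, hier = small_landscape
    return rasterize_hierarchy(hier, stack.spec)


@pytest.fixture(scope="session")
def landscape_200():
    """Default-sized landscape (200×200, 4/16/64 zones)."""
    cfg = LandscapeConfig(seed=11)
    return generate_landscape(cfg)


@pytest.fixture(scope="session")
def zones_200(landscape_200):
    stack, hier = landscape_200
    return rasterize_hierarchy(hier, stack.spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
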