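import numpy as np
import pytest

from agrigpp.districts import aggregate_district, district_gpp_frame
from agrigpp.pipeline import compute_seasonal_gpp
from agrigpp.synthetic import (DEFAULT_COEFFICIENTS, DEFAULT_MONSOON_CROPS,
                               SceneConfig, generate_crop_stats, generate_scene)


@pytest.fixture(scope="session")
def noiseless_config():
    return SceneConfig(grid_rows=20, grid_cols=20, n_districts=6,
                       n_composites=8, noise_sd_ndvi=0.0,
                       noise_sd_production=0.0, rng_seed=11)


@pytest.fixture(scope="session")
def noiseless_scene(noiseless_config):
    return generate_scene(noiseless_config)


@pytest.fixture(scope="session")
def noiseless_stats(noiseless_scene):
    return generate_crop_stats(noiseless_scene, DEFAULT_MONSOON_CROPS,
                               DEFAULT_COEFFICIENTS, production_noise_sd=0.0)


@pytest.fixture(scope="session")
def noiseless_district_frame(noiseless_scene):
    gpp = compute_seasonal_gpp(noiseless_scene)
    agg = aggregate_district(gpp, noiseless_scene.district_labels,
                             noiseless_scene.cropland_mask, "monsoon", 2005)
    return district_gpp_frame(agg)
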