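import numpy as np
import pytest

from lidarval.scene import (SceneConfig, generate_canopy, generate_terrain,
                            make_scene, sample_point_cloud)


@pytest.fixture(scope="session")
def hilly_config():
    """A small sloped, partially forested scene configuration."""
    return SceneConfig(seed=11, mean_slope_deg=20.0, roughness_amplitude=1.0,
                       canopy_cover_fraction=0.6, canopy_height_mean=18.0,
                       canopy_height_sd=4.0)


@pytest.fixture(scope="session")
def hilly_scene(hilly_config):
    return make_scene(hilly_config, (0.0, 0.0, 150.0, 150.0))


@pytest.fixture(scope="session")
def hilly_cloud(hilly_scene, hilly_config):
    return sample_point_cloud(hilly_scene, hilly_config)


@pytest.fixture(scope="session")
def flat_config():
    """Flat bare terrain at constant elevation 500 m, no noise."""
    return SceneConfig(seed=7, mean_slope_deg=0.0, roughness_amplitude=0.0,
                       canopy_cover_fraction=0.0, ground_z_noise_sd=0.0)


@pytest.fixture(scope="session")
def flat_scene(flat_config):
    scene = generate_terrain(flat_config, (0.0, 0.0, 120.0, 120.0))
    scene.dem.data += 500.0
    return generate_canopy(scene, flat_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
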