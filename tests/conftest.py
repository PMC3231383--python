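import dataclasses

import numpy as np
import pytest

from canopyfuse import (
    GardenConfig,
    IlluminationModel,
    default_garden_config,
    generate_scene,
)
from canopyfuse import features, fusion
from canopyfuse.synthetic_scene import small_garden_config


NOISE_FREE = IlluminationModel(
    frame_sd=0.0,
    directional_sd=0.0,
    shaded_reference_prob=0.0,
)


def noise_free(config: GardenConfig) -> GardenConfig:
    """Strip every stochastic spectral degradation from a config."""
    templates = tuple(
        dataclasses.replace(t, spectral_sd=0.0) for t in config.templates
    )
    return dataclasses.replace(config, templates=templates, illumination=NOISE_FREE)


@pytest.fixture(scope="session")
def tiny_config() -> GardenConfig:
    """Four species (2 deciduous, 2 coniferous), three specimens each."""
    return small_garden_config(
        species=(
            "Sorbus aucuparia",
            "Quercus robur",
            "Abies sibirica",
            "Picea pungens",
        ),
        specimens_per_species=3,
    )


@pytest.fixture(scope="session")
def tiny_scene(tiny_config):
    return generate_scene(tiny_config, seed=11)


@pytest.fixture(scope="session")
def tiny_fused(tiny_scene):
    return fusion.fuse(tiny_scene.specimens, tiny_scene.frames, tiny_scene.band_set)


@pytest.fixture(scope="session")
def tiny_table(tiny_scene, tiny_fused):
    return features.build_feature_table(tiny_fused, tiny_scene.band_set)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def garden_config():
    return default_garden_config()
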