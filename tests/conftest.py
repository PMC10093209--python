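import numpy as np
import pytest
from hypothesis import settings

# property tests check theorems that must hold for all inputs; derandomise so
# the suite is reproducible run to run
settings.register_profile("default", derandomize=True)
settings.load_profile("default")

import mifscore as m
from mifscore.pipeline import build_unet_slide, strong_separation_config

INFORMATIVE = ["area", "mean_DAPI", "density", "af_mean_CD3", "env_sd_area"]


@pytest.fixture(scope="session")
def registry():
    return m.FeatureRegistry.default()


@pytest.fixture(scope="session")
def tiled_slide():
    """A jittered multi-tile synthetic slide with truth."""
    config = m.SimulationConfig(seed=3, n_cells_target=300)
    tiles, truth = m.generate_slide(config)
    return config, tiles, truth


@pytest.fixture(scope="session")
def informative_table():
    """20k-cell feature table with five strongly informative features (d=3)."""
    config = m.SimulationConfig(
        seed=100, n_cells_target=20000, informative_features={f: 3.0 for f in INFORMATIVE}
    )
    table, labels = m.generate_feature_table(config)
    return table, labels


@pytest.fixture(scope="session")
def strong_cohort():
    """Four small strongly-separated slides for the image model."""
    return [build_unet_slide(strong_separation_config(seed)) for seed in (11, 12, 13, 14)]
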