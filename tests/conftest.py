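import numpy as np
import pytest

from tercab.gridio import Grid, GridTransform
from tercab.synthetic import HumanPatch, SceneConfig, generate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def unit_grid():
    """3x4 float grid with one nodata cell."""
    values = np.arange(12, dtype=float).reshape(3, 4)
    values[1, 2] = -9999.0
    return Grid(values, nodata=-9999.0,
                transform=GridTransform(0.0, 3.0, 1.0, 1.0), crs="local")


@pytest.fixture(scope="session")
def small_scene():
    """A 24x32 scene with a disturbance patch, shared across tests."""
    cfg = SceneConfig(
        shape=(24, 32),
        seed=7,
        human_patches=[HumanPatch(year=2010, row0=4, col0=6, height=10,
                                  width=10, target_class=7)],
    )
    return generate_scene(cfg)
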