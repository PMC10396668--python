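from datetime import date

import numpy as np
import pytest

from moundscape.scene_io import DEFAULT_BAND_LAYOUT, GridGeometry, SceneRaster
from moundscape.synthetic_data import SimConfig, simulate_study


def make_scene(
    rng=None,
    shape=(10, 12),
    scene_id="S1",
    acq=date(2000, 7, 1),
    dn_low=8000,
    dn_high=20000,
    x_west=0.0,
    y_north=0.0,
    scaled=False,
):
    """Small random DN scene on a simple grid."""
    rng = rng or np.random.default_rng(0)
    grid = GridGeometry(
        x_west=x_west, y_north=y_north, cell_size=30.0,
        n_rows=shape[0], n_cols=shape[1],
    )
    bands = {
        b: np.ma.asarray(rng.integers(dn_low, dn_high, shape).astype(float))
        for b in DEFAULT_BAND_LAYOUT
    }
    return SceneRaster(
        scene_id=scene_id, acquisition_date=acq, wrs_path=35, wrs_row=38,
        grid=grid, bands=bands, scaled=scaled,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_scene(rng):
    return make_scene(rng)


@pytest.fixture(scope="session")
def small_config():
    """Desk-sized study: 3 scene-years, coarse grid, small population."""
    return SimConfig(
        seed=7,
        n_years=3,
        scenes_per_year=8,
        grid_shape=(36, 30),
        n_mounds=60,
        n_anchor_mounds=50,
        n_females_per_year=15,
        n_males_per_year=10,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return simulate_study(small_config)
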