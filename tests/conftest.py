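import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from canopydiv.raster import RasterGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_inventory():
    """Two plots, hand-built records covering all crown classes."""
    return pd.DataFrame(
        {
            "plot_id": ["P1"] * 5 + ["P2"] * 3,
            "species": ["a", "a", "b", "c", "c", "a", "a", "b"],
            "dbh_cm": [10.0, 12.0, 8.0, 5.0, 20.0, 9.0, 15.0, 30.0],
            "height_m": [18.0, 20.0, 15.0, 12.0, 25.0, 14.0, 21.0, 28.0],
            "crown_class": [
                "dominant", "co-dominant", "dominant", "co-dominant", "dominant",
                "dominant", "co-dominant", "dominant",
            ],
            "crown_ew_m": [4.0] * 8,
            "crown_ns_m": [4.0] * 8,
        }
    )


def make_raster(values, res=1.0, origin=None, band_names=None, mask=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[None]
    rows, cols = values.shape[1:]
    if origin is None:
        origin = (0.0, rows * res)
    if band_names is None:
        band_names = tuple(f"band{i + 1}" for i in range(values.shape[0]))
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    return RasterGrid(values, mask, origin, res, band_names)


@pytest.fixture
def plot_box():
    return box(0.0, 0.0, 20.0, 20.0)
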