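import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from shelfhypso import (
    DepthDistributionSpec,
    GridSpec,
    ShelfCellTable,
    bounding_region,
    mask_cells_single,
    synth_bathymetry,
)


def make_cells(depths, areas=None, region="test", depth_max=2000.0) -> ShelfCellTable:
    """Cell table with synthetic coordinates (one cell per record)."""
    depths = np.asarray(depths, dtype=float)
    if areas is None:
        areas = np.ones_like(depths)
    n = len(depths)
    df = pd.DataFrame(
        {
            "lat": np.linspace(0.0, 1.0, n, endpoint=False),
            "lon": np.zeros(n),
            "depth_m": depths,
            "area_km2": np.asarray(areas, dtype=float),
        }
    )
    return ShelfCellTable(df=df, region=region, depth_max=depth_max)


def synth_cells(spec: DepthDistributionSpec, seed=0, n=100, region="synth"):
    """Masked cell table from a synthetic near-equator bathymetry grid."""
    grid = GridSpec(lat_min=-2.5, lat_max=2.5, lon_min=0.0, lon_max=5.0,
                    resolution=5.0 / n)
    bathy, truth = synth_bathymetry(spec, grid, seed=seed)
    cells = mask_cells_single(bathy, bounding_region(grid, name=region))
    return cells, truth


@pytest.fixture(scope="session")
def shallow_spec():
    return DepthDistributionSpec(kind="beta", components=((1.5, 12.0),))


@pytest.fixture(scope="session")
def mid_spec():
    return DepthDistributionSpec(kind="beta", components=((2.0, 2.0),))


@pytest.fixture(scope="session")
def uniform_spec():
    return DepthDistributionSpec(kind="uniform")


@pytest.fixture(scope="session")
def bimodal_spec():
    return DepthDistributionSpec(
        kind="beta-mixture", components=((5.0, 45.0), (45.0, 5.0)), weights=(0.5, 0.5)
    )
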