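"""Shared fixtures: a desk-scale synthetic fixture pair and scenario suite."""

import numpy as np
import pytest

from eutroscen import effluent, synth
from eutroscen.grid import Grid


@pytest.fixture(scope="session")
def small_cfg():
    # Nov 2015 - Oct 2016: one full Nov-Oct year including Aug-Oct
    return synth.SynthConfig(nx=48, ny=36, months=12, seed=7)


@pytest.fixture(scope="session")
def small_records(small_cfg):
    return synth.default_outfalls(small_cfg)


@pytest.fixture(scope="session")
def small_suite(small_records):
    return effluent.build_scenario_suite(small_records)


@pytest.fixture(scope="session")
def small_pair(small_cfg):
    anth, ctrl, grid = synth.make_fixture_pair(small_cfg)
    return anth, ctrl, grid


@pytest.fixture
def simple_grid():
    """Tiny hand-built grid: straight meridional coast on the east, 3-km cells."""
    n = 8
    dlat = 3.0 / 111.195
    lat = 33.0 + np.arange(n) * dlat
    dlon = 3.0 / (111.195 * np.cos(np.radians(33.0)))
    lon = -119.0 + np.arange(n) * dlon
    land = np.zeros((n, n), dtype=bool)
    land[:, -2:] = True
    bathy = np.tile(np.concatenate([np.linspace(500, 50, n - 2), [0, 0]]), (n, 1))
    return Grid(
        lon=lon,
        lat=lat,
        z_centers=np.array([5.0, 15.0, 30.0, 60.0, 120.0, 250.0]),
        z_thickness=np.array([10.0, 10.0, 20.0, 40.0, 80.0, 180.0]),
        bathymetry=bathy,
        land_mask=land,
    )
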