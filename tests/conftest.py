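"""Shared fixtures: small synthetic collections and toy rasters.

All fixtures are generated in memory at test time; nothing is read from
disk except where a test exercises file I/O itself.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pytest

from maxndvi import (GeoGrid, NdviImage, Phenology, SceneID, SelectionPolicy,
                     SimulationConfig, SRImage, simulate_collection)


def make_grid(width: int = 4, height: int = 4, pixel: float = 1.0,
              x0: float = 0.0, y0: float = 100.0, crs: str = "EPSG:32649") -> GeoGrid:
    return GeoGrid.create(x0, y0, pixel, width, height, crs)


def make_sr(red, nir, qa=None, nodata=None, scene=SceneID(125, 34),
            date=dt.date(2021, 8, 1), grid=None) -> SRImage:
    red = np.asarray(red, dtype=np.float32)
    nir = np.asarray(nir, dtype=np.float32)
    if grid is None:
        grid = make_grid(red.shape[1], red.shape[0])
    if qa is None:
        qa = np.zeros(red.shape, dtype=np.uint16)
    if nodata is None:
        nodata = np.zeros(red.shape, dtype=bool)
    return SRImage(scene=scene, date=date, grid=grid, red=red, nir=nir,
                   qa=np.asarray(qa, dtype=np.uint16),
                   nodata_mask=np.asarray(nodata, dtype=bool))


def make_ndvi(values, valid=None, scene=SceneID(125, 34),
              date=dt.date(2021, 8, 1), grid=None) -> NdviImage:
    values = np.asarray(values, dtype=np.float32)
    if grid is None:
        grid = make_grid(values.shape[1], values.shape[0])
    if valid is None:
        valid = np.isfinite(values)
    return NdviImage(scene=scene, date=date, grid=grid, ndvi=values,
                     valid_mask=np.asarray(valid, dtype=bool))


def small_config(**overrides) -> SimulationConfig:
    """A fast, fully featured simulation: 3 scenes of 96 px, 8 dates each."""
    kwargs = dict(seed=7, grid_size=96, cadence_days=28, end_doy=300)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


@pytest.fixture(scope="session")
def default_sim():
    cfg = small_config()
    images, truth = simulate_collection(cfg)
    return cfg, images, truth


@pytest.fixture(scope="session")
def clean_sim():
    """No noise, no clouds, no tone distortion: observations equal truth."""
    cfg = small_config(seed=11, noise_sd=0.0, cloud_fraction_range=(0.0, 0.0),
                       distortion_gain_range=(1.0, 1.0),
                       distortion_gamma_range=(1.0, 1.0),
                       distortion_offset_range=(0.0, 0.0))
    images, truth = simulate_collection(cfg)
    return cfg, images, truth


@pytest.fixture()
def policy_for():
    def _make(cfg: SimulationConfig) -> SelectionPolicy:
        return SelectionPolicy(selectable_scenes=cfg.selectable_scenes)
    return _make
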