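"""Per-pixel median fusion and the end-to-end annual composite.

After calibration every image in the collection estimates the same
peak-season NDVI field, so the per-pixel median over the stack is the
annual-maximum composite; the median also suppresses anomalous residuals
(unscreened cloud, haze).  A raw per-pixel temporal maximum is kept only as
a diagnostic alternative for comparison experiments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cdf_calibration import DEFAULT_BIN_WIDTH, calibrate_collection
from .errors import EmptyCollectionError
from .ndvi_engine import (DateWindow, NdviImage, QaScheme, compute_ndvi,
                          filter_collection, mask_clouds)
from .raster_scene import GeoGrid, RegionOfInterest, SRImage, require_same_grid
from .reference_selector import SelectionPolicy, SelectionReport, select_reference

logger = logging.getLogger(__name__)


@dataclass
class CompositeResult:
    """Fused annual-maximum NDVI plus per-pixel contributing-observation count."""

    ndvi_max: np.ndarray
    count: np.ndarray
    grid: GeoGrid
    year: int

    @property
    def mask(self) -> np.ndarray:
        """True where no observation contributed."""
        return self.count == 0

    def as_ndvi_image(self, scene, date) -> NdviImage:
        return NdviImage(scene=scene, date=date, grid=self.grid,
                         ndvi=self.ndvi_max, valid_mask=~self.mask)


def _stack(images: list[NdviImage], grid: GeoGrid) -> np.ndarray:
    if not images:
        raise EmptyCollectionError("cannot fuse an empty collection")
    require_same_grid(grid, *(img.grid for img in images))
    stack = np.full((len(images), *grid.shape), np.nan, dtype=np.float64)
    for k, img in enumerate(images):
        stack[k][img.valid_mask] = img.ndvi[img.valid_mask]
    return stack


def median_fuse(images: list[NdviImage], grid: GeoGrid, year: int) -> CompositeResult:
    """Per-pixel median of valid values (even counts: mean of the two
    central values); pixels with no valid value are masked."""
    stack = _stack(images, grid)
    count = np.sum(np.isfinite(stack), axis=0).astype(np.int32)
    with np.errstate(all="ignore"):
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", category=RuntimeWarning)
            med = np.nanmedian(stack, axis=0)
    med = med.astype(np.float32)
    med[count == 0] = np.nan
    return CompositeResult(ndvi_max=med, count=count, grid=grid, year=year)


def max_fuse(images: list[NdviImage], grid: GeoGrid, year: int) -> CompositeResult:
    """Diagnostic raw per-pixel temporal maximum (no calibration semantics)."""
    stack = _stack(images, grid)
    count = np.sum(np.isfinite(stack), axis=0).astype(np.int32)
    with np.errstate(all="ignore"):
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", category=RuntimeWarning)
            mx = np.nanmax(stack, axis=0)
    mx = mx.astype(np.float32)
    mx[count == 0] = np.nan
    return CompositeResult(ndvi_max=mx, count=count, grid=grid, year=year)


def composite_annual_max(images: list[SRImage], year: int, window: DateWindow,
                         roi: RegionOfInterest, policy: SelectionPolicy,
                         bin_width: float = DEFAULT_BIN_WIDTH,
                         scheme: QaScheme = QaScheme(),
                         calibration: bool = True,
                         method: str = "quantile",
                         ) -> tuple[CompositeResult, SelectionReport]:
    """Full chain: filter -> mask -> NDVI -> reference selection ->
    CDF calibration -> median fusion.

    ``calibration=False`` skips the CDF matching (used by validation
    experiments to quantify what the calibration buys); everything is
    deterministic given inputs and configuration.
    """
    filtered = filter_collection(images, year, window, roi)
    logger.info("year %d: %d/%d images pass date+ROI filtering", year, len(filtered), len(images))
    if not filtered:
        raise EmptyCollectionError(f"no images for year {year} after filtering")
    grid = require_same_grid(*(img.grid for img in filtered))

    masked = [mask_clouds(img, scheme) for img in filtered]
    ndvi_images = [compute_ndvi(img) for img in masked]

    candidates = [(sr, nd) for sr, nd in zip(masked, ndvi_images)
                  if nd.scene in policy.selectable_scenes]
    report = select_reference(candidates, policy, roi, scheme)
    logger.info("year %d: reference %s %s", year, report.chosen.scene, report.chosen.date)

    if calibration:
        calibrated = calibrate_collection(ndvi_images, report.chosen, roi,
                                          bin_width=bin_width, method=method)
        fuse_inputs = calibrated.images
        logger.info("year %d: calibrated %d images (%d dropped)", year,
                    len(calibrated.images), len(calibrated.dropped))
    else:
        fuse_inputs = [img for img in ndvi_images if img.valid_mask.any()]

    composite = median_fuse(fuse_inputs, grid, year)
    return composite, report
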