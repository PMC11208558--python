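"""Collection filtering, QA cloud/shadow masking, and per-image NDVI.

NDVI = (NIR - RED) / (NIR + RED), computed per pixel on surface reflectance.
Pixels flagged cloud or cloud shadow in the QA bitmask are removed before any
statistic downstream sees them; pixels where NIR + RED <= 0 are masked rather
than producing infinities, and noisy reflectance that pushes NDVI outside its
defined [-1, 1] range is clipped, not discarded.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import GeometryError
from .raster_scene import GeoGrid, RegionOfInterest, SceneID, SRImage


@dataclass
class NdviImage:
    """Single-band NDVI raster with a validity mask, dated and scene-tagged."""

    scene: SceneID
    date: _dt.date
    grid: GeoGrid
    ndvi: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.ndvi.shape != self.grid.shape or self.valid_mask.shape != self.grid.shape:
            from .errors import GridMismatchError
            raise GridMismatchError("ndvi/valid_mask do not conform to grid")
        self.valid_mask = self.valid_mask.astype(bool)

    def replace_values(self, ndvi: np.ndarray) -> "NdviImage":
        return replace(self, ndvi=ndvi)


@dataclass(frozen=True)
class DateWindow:
    """Within-year month window, inclusive on both ends (no wrap)."""

    start_month: int = 4
    end_month: int = 10

    def __post_init__(self) -> None:
        if not (1 <= self.start_month <= self.end_month <= 12):
            raise ValueError("require 1 <= start_month <= end_month <= 12")

    def contains(self, date: _dt.date, year: int) -> bool:
        return date.year == year and self.start_month <= date.month <= self.end_month

    def months(self) -> range:
        return range(self.start_month, self.end_month + 1)


@dataclass(frozen=True)
class QaScheme:
    """Which QA bit positions mark unusable pixels.

    Defaults follow the Landsat Collection-2 QA_PIXEL layout: bit 0 fill,
    bit 3 cloud, bit 4 cloud shadow.  Dilated-cloud and cirrus bits are not
    rejected by default but can be added through ``extra_bits``.
    """

    cloud_bit: int = 3
    shadow_bit: int = 4
    fill_bit: int = 0
    extra_bits: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        bits = (self.cloud_bit, self.shadow_bit, self.fill_bit, *self.extra_bits)
        if len(set(bits)) != len(bits):
            raise ValueError("QA bit positions must be distinct")
        if any(b < 0 or b > 15 for b in bits):
            raise ValueError("QA bit positions must fit a 16-bit word")

    @property
    def reject_mask_word(self) -> int:
        word = (1 << self.cloud_bit) | (1 << self.shadow_bit)
        for b in self.extra_bits:
            word |= 1 << b
        return word

    def flagged(self, qa: np.ndarray) -> np.ndarray:
        """True where the QA word marks cloud, shadow, or an extra bit."""
        return (qa.astype(np.uint32) & self.reject_mask_word) != 0

    def fill(self, qa: np.ndarray) -> np.ndarray:
        """True where the QA word marks fill (no observation)."""
        return (qa.astype(np.uint32) & (1 << self.fill_bit)) != 0


def filter_collection(images: list[SRImage], year: int, window: DateWindow,
                      roi: RegionOfInterest) -> list[SRImage]:
    """Keep images dated inside the year's month window whose footprint
    intersects the ROI; input order is preserved.  May return []."""
    if roi.geometry.is_empty:
        raise GeometryError("ROI is empty")
    kept = []
    for img in images:
        if not window.contains(img.date, year):
            continue
        fp = img.footprint_polygon()
        if fp is None or not fp.intersects(roi.geometry):
            continue
        kept.append(img)
    return kept


def mask_clouds(image: SRImage, scheme: QaScheme = QaScheme()) -> SRImage:
    """Add QA-flagged cloud/shadow pixels to the image's nodata mask.

    Mask growth is monotone: no pixel is ever unmasked.
    """
    return image.with_mask(scheme.flagged(image.qa))


def compute_ndvi(image: SRImage) -> NdviImage:
    """Eq.-of-definition NDVI with degenerate denominators masked.

    Valid pixels are observed pixels with NIR + RED > 0; their NDVI is
    clipped to [-1, 1] after computation.
    """
    red = image.red.astype(np.float64)
    nir = image.nir.astype(np.float64)
    denom = nir + red
    valid = ~image.nodata_mask & (denom > 0)
    ndvi = np.zeros(image.grid.shape, dtype=np.float32)
    np.divide(nir - red, denom, out=ndvi, where=valid, casting="unsafe")
    np.clip(ndvi, -1.0, 1.0, out=ndvi)
    ndvi[~valid] = np.nan
    return NdviImage(scene=image.scene, date=image.date, grid=image.grid,
                     ndvi=ndvi, valid_mask=valid)
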