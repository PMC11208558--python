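"""Scene, grid and raster data model plus GeoTIFF / GeoJSON I/O.

A *scene* is a nominal acquisition footprint on a WRS-like (path, row) grid,
written in the field's zero-padded ``ppprrr`` notation.  An :class:`SRImage`
is one dated surface-reflectance acquisition of a scene — red and
near-infrared reflectance plus a per-pixel quality bitmask — registered to a
:class:`GeoGrid`.  All multi-image operations in this package require
*identical* grids and fail loudly otherwise; there is no silent resampling.

GeoTIFF files are read and written with tifffile.  Georeferencing is conveyed
through the standard ``ModelPixelScale``/``ModelTiepoint`` tags, the nodata
value through the ``GDAL_NODATA`` tag, and the CRS plus band/acquisition
metadata through a JSON ``ImageDescription``.  Files written here open in any
GeoTIFF-aware GIS with correct placement.
"""

from __future__ import annotations

import datetime as _dt
import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon, shape as _shapely_shape
import tifffile

from .errors import GeometryError, GridMismatchError, RasterFormatError

# Landsat Collection-2 Level-2 DN -> reflectance convention.
DEFAULT_REFLECTANCE_SCALE = (2.75e-5, -0.2)

# Reflectance outside this range is physically impossible after scaling.
REFLECTANCE_VALID_RANGE = (-0.2, 1.6)

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


# ---------------------------------------------------------------------------
# Scene identity


@dataclass(frozen=True, order=True)
class SceneID:
    """(path, row) identity of a nominal acquisition footprint."""

    path: int
    row: int

    def __post_init__(self) -> None:
        if not (1 <= self.path <= 999 and 1 <= self.row <= 999):
            raise ValueError(f"path/row must be in [1, 999], got {self.path}/{self.row}")

    def __str__(self) -> str:
        return scene_notation(self)


def scene_notation(scene: SceneID) -> str:
    """Render a scene as the canonical zero-padded ``ppprrr`` string."""
    return f"{scene.path:03d}{scene.row:03d}"


def parse_scene_notation(text: str) -> SceneID:
    """Inverse of :func:`scene_notation` (``"126032"`` -> path 126, row 32)."""
    if not re.fullmatch(r"\d{6}", text):
        raise ValueError(f"scene notation must be 6 digits (ppprrr), got {text!r}")
    return SceneID(path=int(text[:3]), row=int(text[3:]))


# ---------------------------------------------------------------------------
# Geogrid


@dataclass(frozen=True)
class GeoGrid:
    """Affine pixel<->map registration of a raster.

    ``transform`` is the GDAL-style 6-tuple ``(a, b, c, d, e, f)`` mapping the
    *upper-left corner* of pixel (row, col) to map coordinates::

        x = a * col + b * row + c
        y = d * col + e * row + f

    Only axis-aligned, north-up grids (``b == d == 0``, ``e < 0``) are
    supported, which is what the writer emits and the GeoTIFF pixel-scale
    representation can express.
    """

    transform: tuple[float, float, float, float, float, float]
    width: int
    height: int
    crs: str = "EPSG:4326"

    def __post_init__(self) -> None:
        a, b, c, d, e, f = self.transform
        if b != 0 or d != 0 or a <= 0 or e >= 0:
            raise ValueError("only axis-aligned north-up transforms are supported")
        if self.width < 1 or self.height < 1:
            raise ValueError("grid must have positive width and height")

    @classmethod
    def create(cls, x0: float, y0: float, pixel_size: float,
               width: int, height: int, crs: str = "EPSG:4326") -> "GeoGrid":
        return cls((pixel_size, 0.0, x0, 0.0, -pixel_size, y0), width, height, crs)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates (x, y) of every pixel center, each (height, width)."""
        a, _, c, _, e, f = self.transform
        cols = np.arange(self.width)
        rows = np.arange(self.height)
        x = c + (cols + 0.5) * a
        y = f + (rows + 0.5) * e
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(y[:, None], self.shape).copy()

    def bounds_polygon(self) -> Polygon:
        a, _, c, _, e, f = self.transform
        x1 = c + self.width * a
        y1 = f + self.height * e
        return Polygon([(c, f), (x1, f), (x1, y1), (c, y1)])

    def window_polygon(self, row0: int, row1: int, col0: int, col1: int) -> Polygon:
        """Map-space rectangle covering pixel rows [row0, row1) x cols [col0, col1)."""
        a, _, c, _, e, f = self.transform
        xa, xb = c + col0 * a, c + col1 * a
        ya, yb = f + row0 * e, f + row1 * e
        return Polygon([(xa, ya), (xb, ya), (xb, yb), (xa, yb)])


def require_same_grid(*grids: GeoGrid) -> GeoGrid:
    """Assert all grids identical; return the common grid."""
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise GridMismatchError(f"geogrids differ: {first} vs {g}")
    return first


# ---------------------------------------------------------------------------
# Region of interest


@dataclass(frozen=True)
class RegionOfInterest:
    """Polygonal analysis region in the raster CRS."""

    geometry: shapely.Geometry
    name: str = "roi"

    def __post_init__(self) -> None:
        if self.geometry.is_empty or self.geometry.area <= 0:
            raise GeometryError("ROI geometry must be nonempty with finite area")

    @classmethod
    def from_geojson(cls, path: Path | str, name: str | None = None) -> "RegionOfInterest":
        with open(path) as fh:
            gj = json.load(fh)
        if gj.get("type") == "FeatureCollection":
            geoms = [_shapely_shape(feat["geometry"]) for feat in gj["features"]]
            geom = shapely.union_all(geoms)
        elif gj.get("type") == "Feature":
            geom = _shapely_shape(gj["geometry"])
        else:
            geom = _shapely_shape(gj)
        return cls(geom, name=name or Path(path).stem)

    def to_geojson(self, path: Path | str) -> None:
        gj = {
            "type": "Feature",
            "properties": {"name": self.name},
            "geometry": shapely.geometry.mapping(self.geometry),
        }
        with open(path, "w") as fh:
            json.dump(gj, fh)

    def raster_mask(self, grid: GeoGrid) -> np.ndarray:
        """Boolean mask of pixels whose centers fall inside the ROI."""
        x, y = grid.pixel_centers()
        geom = self.geometry
        shapely.prepare(geom)
        return shapely.contains_xy(geom, x.ravel(), y.ravel()).reshape(grid.shape)


# ---------------------------------------------------------------------------
# Surface-reflectance image


@dataclass
class SRImage:
    """One dated, scene-tagged surface-reflectance acquisition.

    ``red`` and ``nir`` are dimensionless reflectances (already scaled),
    ``qa`` is the per-pixel quality bitmask, and ``nodata_mask`` is True where
    there is no observation (file nodata, fill, or physically impossible
    reflectance).  Cloud masking *adds* to ``nodata_mask`` downstream.
    """

    scene: SceneID
    date: _dt.date
    grid: GeoGrid
    red: np.ndarray
    nir: np.ndarray
    qa: np.ndarray
    nodata_mask: np.ndarray

    def __post_init__(self) -> None:
        for name in ("red", "nir", "qa", "nodata_mask"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise GridMismatchError(
                    f"{name} band shape {arr.shape} does not conform to grid {self.grid.shape}")
        self.nodata_mask = self.nodata_mask.astype(bool)

    def with_mask(self, mask: np.ndarray) -> "SRImage":
        """Copy of the image with ``mask`` OR-ed into the nodata mask."""
        return replace(self, nodata_mask=self.nodata_mask | mask)

    def footprint_polygon(self) -> Polygon | None:
        """Map-space bounding rectangle of observed (non-nodata) pixels."""
        observed = ~self.nodata_mask
        if not observed.any():
            return None
        rows = np.flatnonzero(observed.any(axis=1))
        cols = np.flatnonzero(observed.any(axis=0))
        return self.grid.window_polygon(rows[0], rows[-1] + 1, cols[0], cols[-1] + 1)


def flag_invalid_reflectance(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """True where either band is non-finite or outside the physical range."""
    lo, hi = REFLECTANCE_VALID_RANGE
    bad = ~np.isfinite(red) | ~np.isfinite(nir)
    bad |= (red < lo) | (red > hi) | (nir < lo) | (nir > hi)
    return bad


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def _geo_extratags(grid: GeoGrid, nodata_value=None) -> list:
    a, _, c, _, e, f = grid.transform
    tags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (a, -e, 0.0), True),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, c, f, 0.0), True),
    ]
    if nodata_value is not None:
        tags.append((_TAG_GDAL_NODATA, "s", 0, str(nodata_value), True))
    return tags


def _grid_from_page(page, crs: str) -> GeoGrid:
    scale = page.tags.valueof(_TAG_MODEL_PIXEL_SCALE)
    tiepoint = page.tags.valueof(_TAG_MODEL_TIEPOINT)
    if scale is None or tiepoint is None:
        raise RasterFormatError("file lacks GeoTIFF georeferencing tags")
    sx, sy = float(scale[0]), float(scale[1])
    x0, y0 = float(tiepoint[3]), float(tiepoint[4])
    h, w = page.shape[-2], page.shape[-1]
    return GeoGrid((sx, 0.0, x0, 0.0, -sy, y0), w, h, crs)


def write_geotiff(data: np.ndarray, grid: GeoGrid, file_path: Path | str,
                  nodata_value: float, mask: np.ndarray | None = None,
                  crs_metadata: dict | None = None, int1000: bool = False) -> None:
    """Write a single-band raster with georeferencing and a nodata tag.

    ``mask`` pixels (True = invalid) are stored as ``nodata_value``; a
    round-trip through :func:`read_geotiff` restores values, grid and mask.
    ``int1000=True`` stores values scaled by 1000 and rounded to int16 (the
    conventional compact NDVI encoding); ``nodata_value`` is then ignored in
    favour of -32768.
    """
    if data.shape != grid.shape:
        raise GridMismatchError(f"data shape {data.shape} does not conform to grid {grid.shape}")
    if int1000:
        scaled = np.round(np.asarray(data, dtype=np.float64) * 1000.0)
        out = np.where(np.isfinite(scaled), scaled, -32768).astype(np.int16)
        nodata_value = -32768
    else:
        out = np.array(data, copy=True)
    if mask is not None:
        out[mask] = nodata_value
    desc = {"crs": grid.crs}
    if crs_metadata:
        desc.update(crs_metadata)
    tifffile.imwrite(
        file_path, out,
        description=json.dumps(desc),
        extratags=_geo_extratags(grid, nodata_value),
    )


def read_geotiff(file_path: Path | str) -> tuple[np.ma.MaskedArray, GeoGrid, float]:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`."""
    with tifffile.TiffFile(file_path) as tif:
        page = tif.pages[0]
        desc = _read_description(page)
        grid = _grid_from_page(page, desc.get("crs", "EPSG:4326"))
        nodata_text = page.tags.valueof(_TAG_GDAL_NODATA)
        data = page.asarray()
    if nodata_text is None:
        return np.ma.MaskedArray(data, mask=np.zeros(data.shape, bool)), grid, float("nan")
    nodata = float(nodata_text)
    if np.issubdtype(data.dtype, np.integer):
        mask = data == int(nodata)
    else:
        mask = data == nodata if np.isfinite(nodata) else ~np.isfinite(data)
    return np.ma.MaskedArray(data, mask=mask), grid, nodata


def _read_description(page) -> dict:
    raw = page.tags.valueof(270)  # ImageDescription
    if not raw:
        return {}
    try:
        parsed = json.loads(raw)
        return parsed if isinstance(parsed, dict) else {}
    except (json.JSONDecodeError, TypeError):
        return {}


def write_sr_geotiff(image: SRImage, file_path: Path | str,
                     scale: tuple[float, float] = DEFAULT_REFLECTANCE_SCALE,
                     dn_nodata: int = 0) -> None:
    """Write an SR acquisition as a 3-page (red, nir, qa) DN GeoTIFF.

    Reflectance is encoded back to uint16 DNs with the inverse of ``scale``
    so the file matches the convention :func:`read_sr_image` expects.
    """
    gain, offset = scale

    def _encode(band: np.ndarray) -> np.ndarray:
        dn = np.round((band - offset) / gain)
        dn = np.clip(dn, 1, 65535).astype(np.uint16)  # DN 0 reserved for nodata
        dn[image.nodata_mask] = dn_nodata
        return dn

    desc = {
        "crs": image.grid.crs,
        "bands": ["red", "nir", "qa"],
        "scene": scene_notation(image.scene),
        "date": image.date.isoformat(),
        "gain": gain,
        "offset": offset,
        "dn_nodata": dn_nodata,
    }
    with tifffile.TiffWriter(file_path) as tw:
        tw.write(_encode(image.red), description=json.dumps(desc),
                 extratags=_geo_extratags(image.grid, dn_nodata))
        tw.write(_encode(image.nir))
        tw.write(image.qa.astype(np.uint16))


def read_sr_image(file_path: Path | str, scene: SceneID | None = None,
                  date: _dt.date | None = None,
                  scale: tuple[float, float] | None = None) -> SRImage:
    """Read a 3-band (red, nir, qa) surface-reflectance GeoTIFF.

    Reflectance = DN * gain + offset.  ``scene``, ``date`` and ``scale``
    override the file's embedded metadata when given; a file without a QA
    band raises :class:`RasterFormatError`.
    """
    with tifffile.TiffFile(file_path) as tif:
        if len(tif.pages) < 3:
            raise RasterFormatError(
                f"{file_path}: expected red, nir and qa bands, found {len(tif.pages)} band(s)")
        page0 = tif.pages[0]
        desc = _read_description(page0)
        grid = _grid_from_page(page0, desc.get("crs", "EPSG:4326"))
        red_dn = tif.pages[0].asarray()
        nir_dn = tif.pages[1].asarray()
        qa = tif.pages[2].asarray()

    if scale is None:
        if "gain" in desc and "offset" in desc:
            scale = (float(desc["gain"]), float(desc["offset"]))
        else:
            scale = DEFAULT_REFLECTANCE_SCALE
    gain, offset = scale
    dn_nodata = int(desc.get("dn_nodata", 0))
    nodata_text = page0.tags.valueof(_TAG_GDAL_NODATA)
    if nodata_text is not None:
        dn_nodata = int(float(nodata_text))

    if scene is None:
        if "scene" not in desc:
            raise RasterFormatError(f"{file_path}: scene not given and absent from metadata")
        scene = parse_scene_notation(desc["scene"])
    if date is None:
        if "date" not in desc:
            raise RasterFormatError(f"{file_path}: date not given and absent from metadata")
        date = _dt.date.fromisoformat(desc["date"])

    nodata = (red_dn == dn_nodata) | (nir_dn == dn_nodata)
    red = red_dn.astype(np.float32) * gain + offset
    nir = nir_dn.astype(np.float32) * gain + offset
    nodata |= flag_invalid_reflectance(red, nir)
    return SRImage(scene=scene, date=date, grid=grid, red=red, nir=nir,
                   qa=qa, nodata_mask=nodata)


# ---------------------------------------------------------------------------
# Alignment utility (synthetic fixtures only — no reprojection engine)


def resample_nearest(data: np.ndarray, src_grid: GeoGrid, dst_grid: GeoGrid,
                     fill) -> np.ndarray:
    """Nearest-neighbour re-gridding between two grids in the same CRS.

    Intended for aligning synthetic fixtures; not a reprojection engine
    (both grids must share a CRS).
    """
    if src_grid.crs != dst_grid.crs:
        raise GridMismatchError("resample_nearest does not reproject between CRSs")
    sa, _, sc, _, se, sf = src_grid.transform
    x, y = dst_grid.pixel_centers()
    col = np.floor((x - sc) / sa).astype(int)
    row = np.floor((y - sf) / se).astype(int)
    inside = (col >= 0) & (col < src_grid.width) & (row >= 0) & (row < src_grid.height)
    out = np.full(dst_grid.shape, fill, dtype=data.dtype)
    out[inside] = data[row[inside], col[inside]]
    return out
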