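"""Synthetic multi-scene surface-reflectance collections with known truth.

The generator emulates the statistical structure the compositing algorithm
relies on: overlapping rectangular scene footprints on a (path, row)
acquisition grid, a shared spatially-correlated latent greenness field mixed
over a few land-cover classes (giving the multimodal NDVI histograms real
scenes have), a seasonal phenology curve peaking in summer, per-acquisition
monotone radiometric tone distortions (the differences the calibration
removes), spatially coherent cloud/shadow masks of controllable fraction,
and additive pixel noise.  Everything is deterministic given the seed.

Latent NDVI is inverted to a (red, nir) reflectance pair by fixing
nir + red = 0.6 and solving the two bands — simple and exactly invertible.
Scenes listed in ``reference_scenes`` carry identity tone at every date:
the latent truth is expressed in the reference radiometry, which is what
makes "ground-truth recovery" a well-posed question for the composite.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy import ndimage

from .errors import ConfigError, GeometryError
from .fusion import CompositeResult
from .ndvi_engine import NdviImage, QaScheme
from .raster_scene import GeoGrid, RegionOfInterest, SceneID, SRImage

BAND_SUM = 0.6  # fixed nir + red used by the NDVI -> reflectance inversion


@dataclass(frozen=True)
class Phenology:
    """Gaussian seasonal greenness curve, peaking in summer.

    latent NDVI = baseline + amplitude * season(doy) * greenness, with
    greenness in [0, 1], so values stay within [-1, 1] whenever
    baseline + amplitude <= 1.
    """

    peak_doy: int = 213  # Aug 1 (non-leap)
    sigma_days: float = 55.0
    amplitude: float = 0.55
    baseline: float = 0.15

    def __post_init__(self) -> None:
        if not (-1.0 <= self.baseline and self.baseline + self.amplitude <= 1.0):
            raise ConfigError("phenology must keep latent NDVI within [-1, 1]")

    def season(self, doy: int) -> float:
        return math.exp(-((doy - self.peak_doy) ** 2) / (2.0 * self.sigma_days ** 2))

    def latent(self, greenness: np.ndarray, doy: int) -> np.ndarray:
        return self.baseline + self.amplitude * self.season(doy) * greenness


@dataclass(frozen=True)
class ToneDistortion:
    """Monotone value-wise tone function applied in reflectance space:
    r -> clip(gain * r**gamma + offset, 0, 1)."""

    gain: float = 1.0
    gamma: float = 1.0
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.gamma <= 0 or self.offset < 0:
            raise ConfigError("tone distortion must be monotone on [0, 1]")

    @property
    def is_identity(self) -> bool:
        return self.gain == 1.0 and self.gamma == 1.0 and self.offset == 0.0

    def apply(self, reflectance: np.ndarray) -> np.ndarray:
        out = self.gain * np.power(np.clip(reflectance, 0.0, 1.0), self.gamma) + self.offset
        return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated year.

    Defaults: three 192-px scenes — 125034, 125035 (same path, the
    designated selectable/reference scenes) and 126034 — overlapping by
    35%, a 16-day acquisition cadence from April to October with a 7-day
    stagger per path step, NDVI noise sd 0.01, cloud+shadow fractions drawn
    uniformly in [0.1, 0.4], and per-acquisition tone distortions with gain
    in [0.9, 1.1], gamma in [0.85, 1.2] and reflectance offset in [0, 0.05]
    on non-reference scenes.

    The greenness correlation length (1 px = 30 m, i.e. vegetation patches
    of a few pixels) is chosen so a footprint holds a number of independent
    field patches comparable, after scaling, to a real scene's — the
    statistic that governs how similar two overlapping footprints'
    value distributions are, which is what CDF matching relies on.
    """

    seed: int = 0
    grid_size: int = 192
    scenes: tuple[SceneID, ...] = (SceneID(125, 34), SceneID(125, 35), SceneID(126, 34))
    overlap: float = 0.35
    year: int = 2021
    start_doy: int = 101
    end_doy: int = 300
    cadence_days: int = 16
    path_stagger_days: int = 7
    phenology: Phenology = field(default_factory=Phenology)
    noise_sd: float = 0.01
    correlation_length: float = 1.0
    landcover_levels: tuple[float, ...] = (0.2, 0.55, 0.9)
    landcover_proportions: tuple[float, ...] = (0.30, 0.45, 0.25)
    cloud_fraction_range: tuple[float, float] = (0.10, 0.40)
    cloud_blob_sigma: float = 8.0
    cloud_fractions: dict | None = None  # (SceneID, date) -> fraction override
    distortion_gain_range: tuple[float, float] = (0.90, 1.10)
    distortion_gamma_range: tuple[float, float] = (0.85, 1.20)
    distortion_offset_range: tuple[float, float] = (0.0, 0.05)
    distortions: dict | None = None  # (SceneID, date) -> ToneDistortion override
    reference_scenes: tuple[SceneID, ...] | None = None  # default scenes[:2]
    dates: dict | None = None  # SceneID -> tuple of dates override
    pixel_size: float = 30.0
    origin: tuple[float, float] = (500000.0, 4_000_000.0)
    crs: str = "EPSG:32649"

    def __post_init__(self) -> None:
        if not (0.0 < self.overlap < 1.0):
            raise ConfigError("overlap must be in (0, 1)")
        if len(self.landcover_levels) != len(self.landcover_proportions):
            raise ConfigError("landcover levels/proportions length mismatch")
        if abs(sum(self.landcover_proportions) - 1.0) > 1e-9:
            raise ConfigError("landcover proportions must sum to 1")
        lo, hi = self.cloud_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("cloud fractions must lie in [0, 1]")
        if not self.scenes:
            raise ConfigError("at least one scene required")

    # -- geometry -----------------------------------------------------------

    @property
    def selectable_scenes(self) -> tuple[SceneID, ...]:
        if self.reference_scenes is not None:
            return self.reference_scenes
        return self.scenes[: min(2, len(self.scenes))]

    def footprint_offsets(self) -> dict[SceneID, tuple[int, int]]:
        """(row_offset, col_offset) of each scene on the union grid."""
        step = int(round((1.0 - self.overlap) * self.grid_size))
        if step <= 0 or step >= self.grid_size:
            raise ConfigError("overlap geometry infeasible for this grid size")
        min_path = min(s.path for s in self.scenes)
        min_row = min(s.row for s in self.scenes)
        return {s: ((s.row - min_row) * step, (s.path - min_path) * step)
                for s in self.scenes}

    def union_grid(self) -> GeoGrid:
        offs = self.footprint_offsets()
        height = max(r for r, _ in offs.values()) + self.grid_size
        width = max(c for _, c in offs.values()) + self.grid_size
        x0, y0 = self.origin
        return GeoGrid.create(x0, y0, self.pixel_size, width, height, self.crs)

    def footprints(self) -> dict[SceneID, tuple[slice, slice]]:
        offs = self.footprint_offsets()
        return {s: (slice(r, r + self.grid_size), slice(c, c + self.grid_size))
                for s, (r, c) in offs.items()}

    def acquisition_dates(self) -> dict[SceneID, tuple[_dt.date, ...]]:
        if self.dates is not None:
            return {s: tuple(sorted(self.dates[s])) for s in self.scenes}
        jan1 = _dt.date(self.year, 1, 1)
        min_path = min(s.path for s in self.scenes)
        out = {}
        for s in self.scenes:
            stagger = (s.path - min_path) * self.path_stagger_days
            doys = range(self.start_doy + stagger, self.end_doy + 1, self.cadence_days)
            out[s] = tuple(jan1 + _dt.timedelta(days=d - 1) for d in doys)
        return out

    def roi(self) -> RegionOfInterest:
        """Union of the scene footprints, the natural analysis region."""
        grid = self.union_grid()
        polys = [grid.window_polygon(rs.start, rs.stop, cs.start, cs.stop)
                 for rs, cs in self.footprints().values()]
        return RegionOfInterest(shapely.union_all(polys), name="synthetic-base")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated collection."""

    latent_max_ndvi: np.ndarray
    per_image_truth: dict  # (SceneID, date) -> NdviImage (undistorted, noise-free)
    greenness: np.ndarray
    grid: GeoGrid
    footprints: dict  # SceneID -> (row_slice, col_slice)
    tones: dict = field(default_factory=dict)  # (SceneID, date) -> ToneDistortion
    cloud_fractions: dict = field(default_factory=dict)  # (SceneID, date) -> float


def _correlated_field(rng: np.random.Generator, shape: tuple[int, int],
                      sigma: float) -> np.ndarray:
    """Zero-mean, unit-variance low-pass-filtered Gaussian noise."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    return (field_ - field_.mean()) / field_.std()


def _greenness_field(rng: np.random.Generator, config: SimulationConfig,
                     shape: tuple[int, int]) -> np.ndarray:
    """Land-cover-class mixture over a smooth latent field, in [0, 1]."""
    base = _correlated_field(rng, shape, config.correlation_length)
    ranks = np.argsort(np.argsort(base.ravel())).reshape(shape)
    uniform = (ranks + 0.5) / base.size
    thresholds = np.cumsum(config.landcover_proportions)
    classes = np.searchsorted(thresholds, uniform, side="right")
    classes = np.clip(classes, 0, len(config.landcover_levels) - 1)
    levels = np.asarray(config.landcover_levels)[classes]
    within = _correlated_field(rng, shape, config.correlation_length * 2)
    return np.clip(levels + 0.10 * within, 0.02, 0.98)


def _coherent_mask(rng: np.random.Generator, footprint_shape: tuple[int, int],
                   fraction: float, sigma: float) -> np.ndarray:
    """Spatially coherent boolean mask hitting the requested fraction."""
    if fraction <= 0:
        return np.zeros(footprint_shape, dtype=bool)
    field_ = _correlated_field(rng, footprint_shape, sigma)
    threshold = np.quantile(field_, fraction)
    return field_ < threshold


def ndvi_to_reflectance(ndvi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Invert NDVI to (red, nir) with the fixed band-sum convention."""
    nir = BAND_SUM * (1.0 + ndvi) / 2.0
    red = BAND_SUM * (1.0 - ndvi) / 2.0
    return red, nir


def simulate_collection(config: SimulationConfig) -> tuple[list[SRImage], SyntheticTruth]:
    """Generate the dated, distorted, clouded SR collection plus its truth."""
    rng = np.random.default_rng(config.seed)
    grid = config.union_grid()
    shape = grid.shape
    footprints = config.footprints()
    dates = config.acquisition_dates()
    phen = config.phenology
    scheme = QaScheme()

    greenness = _greenness_field(rng, config, shape)

    all_doys = sorted({d.timetuple().tm_yday for ds in dates.values() for d in ds})
    season_max = max(phen.season(doy) for doy in all_doys)
    latent_max = (phen.baseline + phen.amplitude * season_max * greenness).astype(np.float32)

    images: list[SRImage] = []
    per_image_truth: dict = {}
    tones: dict = {}
    fractions: dict = {}
    gain_lo, gain_hi = config.distortion_gain_range
    gamma_lo, gamma_hi = config.distortion_gamma_range
    off_lo, off_hi = config.distortion_offset_range
    cf_lo, cf_hi = config.cloud_fraction_range

    for scene in config.scenes:
        rs, cs = footprints[scene]
        fp_shape = (rs.stop - rs.start, cs.stop - cs.start)
        for date in dates[scene]:
            key = (scene, date)
            doy = date.timetuple().tm_yday

            # Draws happen in a fixed order so the collection is reproducible.
            if config.distortions is not None and key in config.distortions:
                tone = config.distortions[key]
                rng.uniform(size=3)  # keep the draw sequence aligned
            elif scene in config.selectable_scenes:
                tone = ToneDistortion()
                rng.uniform(size=3)
            else:
                draws = rng.uniform(size=3)
                tone = ToneDistortion(
                    gain=gain_lo + draws[0] * (gain_hi - gain_lo),
                    gamma=gamma_lo + draws[1] * (gamma_hi - gamma_lo),
                    offset=off_lo + draws[2] * (off_hi - off_lo))
            if config.cloud_fractions is not None and key in config.cloud_fractions:
                fraction = float(config.cloud_fractions[key])
                rng.uniform()
            else:
                fraction = float(cf_lo + rng.uniform() * (cf_hi - cf_lo))
            tones[key] = tone
            fractions[key] = fraction

            latent = phen.latent(greenness, doy)
            truth_ndvi = np.full(shape, np.nan, dtype=np.float32)
            truth_valid = np.zeros(shape, dtype=bool)
            truth_ndvi[rs, cs] = latent[rs, cs]
            truth_valid[rs, cs] = True
            per_image_truth[key] = NdviImage(scene=scene, date=date, grid=grid,
                                             ndvi=truth_ndvi, valid_mask=truth_valid)

            observed = latent + (rng.standard_normal(shape) * config.noise_sd
                                 if config.noise_sd > 0 else 0.0)
            observed = np.clip(observed, -1.0, 1.0)
            red, nir = ndvi_to_reflectance(observed)
            red = tone.apply(red)
            nir = tone.apply(nir)

            outside = np.ones(shape, dtype=bool)
            outside[rs, cs] = False

            qa = np.zeros(shape, dtype=np.uint16)
            qa[outside] = 1 << scheme.fill_bit
            cloud = _coherent_mask(rng, fp_shape, fraction * 0.8,
                                   config.cloud_blob_sigma)
            shadow = _coherent_mask(rng, fp_shape, fraction * 0.2,
                                    config.cloud_blob_sigma)
            qa_fp = qa[rs, cs]
            qa_fp[cloud] |= 1 << scheme.cloud_bit
            qa_fp[shadow] |= 1 << scheme.shadow_bit
            qa[rs, cs] = qa_fp

            red_band = np.zeros(shape, dtype=np.float32)
            nir_band = np.zeros(shape, dtype=np.float32)
            red_band[rs, cs] = red[rs, cs]
            nir_band[rs, cs] = nir[rs, cs]

            images.append(SRImage(scene=scene, date=date, grid=grid,
                                  red=red_band, nir=nir_band, qa=qa,
                                  nodata_mask=outside.copy()))

    truth = SyntheticTruth(latent_max_ndvi=latent_max,
                           per_image_truth=per_image_truth,
                           greenness=greenness, grid=grid,
                           footprints=footprints, tones=tones,
                           cloud_fractions=fractions)
    return images, truth


# ---------------------------------------------------------------------------
# Fixture directories (GeoTIFFs + manifest), so the CLI runs on synthetic
# collections exactly as it would on real data.


def write_fixture_dir(images: list[SRImage], roi: RegionOfInterest, directory,
                      truth: SyntheticTruth | None = None,
                      seed: int | None = None, year: int | None = None) -> dict:
    """Write a collection as per-acquisition SR GeoTIFFs plus manifest.json.

    Returns the manifest dictionary.  File and record order is sorted by
    (scene, date) so identical inputs produce byte-identical manifests.
    """
    import json
    from pathlib import Path

    from .raster_scene import scene_notation, write_geotiff, write_sr_geotiff

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    roi.to_geojson(directory / "roi.geojson")
    records = []
    for img in sorted(images, key=lambda im: (im.scene, im.date)):
        name = f"{scene_notation(img.scene)}_{img.date.isoformat()}.tif"
        write_sr_geotiff(img, directory / name)
        rec = {"scene": scene_notation(img.scene), "date": img.date.isoformat(),
               "file": name}
        if truth is not None:
            key = (img.scene, img.date)
            tone = truth.tones.get(key)
            if tone is not None:
                rec["distortion"] = {"gain": tone.gain, "gamma": tone.gamma,
                                     "offset": tone.offset}
            if key in truth.cloud_fractions:
                rec["cloud_fraction"] = truth.cloud_fractions[key]
        records.append(rec)
    if truth is not None:
        write_geotiff(truth.latent_max_ndvi, truth.grid,
                      directory / "latent_max.tif", nodata_value=-9999.0)
    manifest = {"roi": "roi.geojson", "images": records}
    if seed is not None:
        manifest["seed"] = seed
    if year is not None:
        manifest["year"] = year
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_fixture_dir(directory) -> tuple[list[SRImage], RegionOfInterest, dict]:
    """Read back a fixture directory written by :func:`write_fixture_dir`."""
    import json
    from pathlib import Path

    from .raster_scene import read_sr_image

    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    roi = RegionOfInterest.from_geojson(directory / manifest["roi"])
    images = [read_sr_image(directory / rec["file"]) for rec in manifest["images"]]
    return images, roi, manifest


# ---------------------------------------------------------------------------
# Seam diagnostics


def scene_boundaries(truth: SyntheticTruth) -> list[tuple[str, int]]:
    """Interior footprint edges, as ("col", c) / ("row", r) boundary lines
    between pixel columns c-1 | c (rows r-1 | r)."""
    height, width = truth.grid.shape
    bounds: set[tuple[str, int]] = set()
    for rs, cs in truth.footprints.values():
        for c in (cs.start, cs.stop):
            if 0 < c < width:
                bounds.add(("col", c))
        for r in (rs.start, rs.stop):
            if 0 < r < height:
                bounds.add(("row", r))
    return sorted(bounds)


def seam_profile(composite: CompositeResult, truth: SyntheticTruth,
                 boundary: tuple[str, int]) -> tuple[float, float]:
    """Quantify the mosaic-line artifact across one boundary.

    Returns ``(mean_abs_step, rmse_vs_truth)``.  The step for a straddling
    pixel pair is the composite's across-boundary difference minus the
    latent truth's difference — the artificial discontinuity in excess of
    the natural field gradient — averaged in absolute value over pairs
    where both sides carry observations.  ``rmse_vs_truth`` scores the whole
    composite against the latent annual-maximum field.
    """
    axis, index = boundary
    height, width = composite.grid.shape
    if composite.grid != truth.grid:
        raise GeometryError("composite and truth are on different grids")
    limit = width if axis == "col" else height
    if axis not in ("col", "row") or not (1 <= index <= limit - 1):
        raise GeometryError(f"boundary {boundary} outside grid")

    comp = composite.ndvi_max.astype(np.float64)
    ref = truth.latent_max_ndvi.astype(np.float64)
    valid = ~composite.mask
    if axis == "col":
        a, b = (slice(None), index - 1), (slice(None), index)
    else:
        a, b = (index - 1, slice(None)), (index, slice(None))
    pair_ok = valid[a] & valid[b]
    if not pair_ok.any():
        return float("nan"), _composite_rmse(comp, ref, valid)
    step = (comp[a] - comp[b]) - (ref[a] - ref[b])
    return float(np.abs(step[pair_ok]).mean()), _composite_rmse(comp, ref, valid)


def _composite_rmse(comp: np.ndarray, ref: np.ndarray, valid: np.ndarray) -> float:
    diff = comp[valid] - ref[valid]
    return float(np.sqrt(np.mean(diff ** 2))) if diff.size else float("nan")
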