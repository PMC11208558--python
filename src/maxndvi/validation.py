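"""Leave-one-scene-out accuracy, the image-distance metric, and the
month-by-month calibration experiment.

The accuracy protocol withholds the acquisition that shares the reference
image's date in a nearby scene (the "true" image), reconstructs it with the
full pipeline (the "predicted" image), and scores the root-mean-square error
over co-valid pixels.  Image distance |ΔPath| + |ΔRow| summarizes how far a
calibrated scene sits from the reference on the acquisition grid.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cdf_calibration import (DEFAULT_BIN_WIDTH, apply_mapping, compute_cdf,
                              fit_mapping)
from .errors import NoValidPixelsError
from .fusion import composite_annual_max, median_fuse
from .ndvi_engine import (DateWindow, NdviImage, QaScheme, compute_ndvi,
                          mask_clouds)
from .raster_scene import (RegionOfInterest, SceneID, SRImage,
                           require_same_grid, scene_notation)
from .reference_selector import SelectionPolicy


@dataclass
class ValidationPair:
    """Predicted/true NDVI image pair restricted to co-valid pixels."""

    predicted: NdviImage
    truth: NdviImage

    def __post_init__(self) -> None:
        require_same_grid(self.predicted.grid, self.truth.grid)
        self.covalid = self.predicted.valid_mask & self.truth.valid_mask
        self.n = int(self.covalid.sum())
        if self.n < 1:
            raise NoValidPixelsError("validation pair has no co-valid pixels")


@dataclass
class MonthlyRmseTable:
    """(month, n_images_used, rmse) rows of the imaging-time experiment."""

    rows: pd.DataFrame

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def best_month(self) -> int:
        valid = self.rows.dropna(subset=["rmse"])
        return int(valid.loc[valid["rmse"].idxmin(), "month"])


def rmse(pair: ValidationPair, formula: str = "standard") -> float:
    """RMSE between predicted and true images over co-valid pixels.

    ``"standard"`` is sqrt(mean(squared error)); ``"as_printed"`` divides the
    root of the summed squares by n instead (a literal reading of one common
    typesetting of the formula, kept selectable for transparency — it scales
    like 1/sqrt(n) and is not comparable across image sizes).
    """
    diff = (pair.predicted.ndvi[pair.covalid].astype(np.float64)
            - pair.truth.ndvi[pair.covalid].astype(np.float64))
    ss = float(np.sum(diff ** 2))
    if formula == "standard":
        return float(np.sqrt(ss / pair.n))
    if formula == "as_printed":
        return float(np.sqrt(ss) / pair.n)
    raise ValueError(f"unknown RMSE formula {formula!r}")


def image_distance(cal: SceneID, ref: SceneID) -> int:
    """|Path_cal − Path_ref| + |Row_cal − Row_ref| in scene steps."""
    return abs(cal.path - ref.path) + abs(cal.row - ref.row)


def _find_image(images: list[SRImage], scene: SceneID, date: _dt.date) -> SRImage:
    for img in images:
        if img.scene == scene and img.date == date:
            return img
    raise LookupError(f"no image for scene {scene_notation(scene)} on {date}")


def _truth_ndvi(image: SRImage, scheme: QaScheme) -> NdviImage:
    return compute_ndvi(mask_clouds(image, scheme))


def leave_one_out_experiment(images: list[SRImage], year: int,
                             window: DateWindow, roi: RegionOfInterest,
                             policy: SelectionPolicy,
                             held_out: tuple[SceneID, _dt.date],
                             bin_width: float = DEFAULT_BIN_WIDTH,
                             scheme: QaScheme = QaScheme(),
                             calibration: bool = True,
                             formula: str = "standard",
                             ) -> tuple[ValidationPair, float]:
    """Withhold one (scene, date) acquisition, rebuild the composite from the
    rest, and score it against the withheld image's NDVI.

    Only the exact scene+date match is removed; other dates of the same
    scene stay in the collection.  The composite is restricted to the
    withheld footprint through the co-valid mask of the returned pair.
    """
    scene, date = held_out
    truth_sr = _find_image(images, scene, date)
    remaining = [img for img in images if not (img.scene == scene and img.date == date)]
    composite, report = composite_annual_max(
        remaining, year, window, roi, policy, bin_width=bin_width,
        scheme=scheme, calibration=calibration)
    truth = _truth_ndvi(truth_sr, scheme)
    roi_mask = roi.raster_mask(truth.grid)
    truth_in_roi = NdviImage(scene=truth.scene, date=truth.date, grid=truth.grid,
                             ndvi=truth.ndvi, valid_mask=truth.valid_mask & roi_mask)
    predicted = composite.as_ndvi_image(scene=report.chosen.scene, date=report.chosen.date)
    pair = ValidationPair(predicted=predicted, truth=truth_in_roi)
    return pair, rmse(pair, formula)


def closest_in_time(images: list[SRImage], scene: SceneID,
                    target_date: _dt.date) -> SRImage:
    """The scene's acquisition closest to ``target_date`` by absolute day
    difference, ties broken toward the earlier image."""
    candidates = [img for img in images if img.scene == scene]
    if not candidates:
        raise LookupError(f"no images for scene {scene_notation(scene)}")
    return min(candidates, key=lambda im: (abs((im.date - target_date).days), im.date))


def scene_accuracy_report(images: list[SRImage], year: int, window: DateWindow,
                          roi: RegionOfInterest, policy: SelectionPolicy,
                          bin_width: float = DEFAULT_BIN_WIDTH,
                          scheme: QaScheme = QaScheme(),
                          formula: str = "standard") -> pd.DataFrame:
    """Per-scene applicability report: for every non-reference scene, hold
    out its acquisition closest in time to the reference and score the
    reconstruction.  Columns: scene, date, image_distance, n_covalid, rmse.
    """
    _, report = composite_annual_max(images, year, window, roi, policy,
                                     bin_width=bin_width, scheme=scheme)
    ref = report.chosen
    rows = []
    scenes = sorted({img.scene for img in images})
    for scene in scenes:
        if scene == ref.scene:
            continue
        truth_sr = closest_in_time(images, scene, ref.date)
        pair, value = leave_one_out_experiment(
            images, year, window, roi, policy,
            held_out=(scene, truth_sr.date), bin_width=bin_width,
            scheme=scheme, formula=formula)
        rows.append({
            "scene": scene_notation(scene),
            "date": truth_sr.date,
            "image_distance": image_distance(scene, ref.scene),
            "n_covalid": pair.n,
            "rmse": value,
        })
    return pd.DataFrame(rows)


def monthly_calibration_experiment(images: list[SRImage], year: int,
                                   window: DateWindow, roi: RegionOfInterest,
                                   policy: SelectionPolicy,
                                   held_out_scene: SceneID | None = None,
                                   bin_width: float = DEFAULT_BIN_WIDTH,
                                   scheme: QaScheme = QaScheme(),
                                   formula: str = "standard") -> MonthlyRmseTable:
    """Month-by-month accuracy of the calibration.

    The true image is the held-out scene's acquisition on the reference
    date; it is removed, and for every month in the window the held-out
    scene's image(s) of that month are calibrated against the reference
    (median-fused within the month when there are several) and scored
    against the true image.  Months with no images report a null RMSE.
    """
    composite, report = composite_annual_max(images, year, window, roi, policy,
                                             bin_width=bin_width, scheme=scheme)
    ref = report.chosen
    if held_out_scene is None:
        others = sorted({img.scene for img in images
                         if img.scene != ref.scene
                         and any(im.scene == img.scene and im.date == ref.date
                                 for im in images)},
                        key=lambda s: image_distance(s, ref.scene))
        if not others:
            raise LookupError("no adjacent scene shares the reference date")
        held_out_scene = others[0]

    truth_sr = _find_image(images, held_out_scene, ref.date)
    truth = _truth_ndvi(truth_sr, scheme)
    roi_mask = roi.raster_mask(truth.grid)
    truth = NdviImage(scene=truth.scene, date=truth.date, grid=truth.grid,
                      ndvi=truth.ndvi, valid_mask=truth.valid_mask & roi_mask)

    ref_cdf = compute_cdf(ref, roi, bin_width)
    rows = []
    for month in window.months():
        month_images = [img for img in images
                        if img.scene == held_out_scene
                        and img.date.year == year and img.date.month == month
                        and img.date != truth_sr.date]
        calibrated = []
        for sr in month_images:
            nd = _truth_ndvi(sr, scheme)
            try:
                src_cdf = compute_cdf(nd, roi, bin_width)
            except NoValidPixelsError:
                continue
            mapping = fit_mapping(src_cdf, ref_cdf)
            calibrated.append(apply_mapping(nd, mapping))
        if not calibrated:
            rows.append({"month": month, "n_images_used": 0, "rmse": np.nan})
            continue
        fused = median_fuse(calibrated, truth.grid, year)
        predicted = fused.as_ndvi_image(scene=held_out_scene, date=truth_sr.date)
        pair = ValidationPair(predicted=predicted, truth=truth)
        rows.append({"month": month, "n_images_used": len(calibrated),
                     "rmse": rmse(pair, formula)})
    return MonthlyRmseTable(rows=pd.DataFrame(rows))
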