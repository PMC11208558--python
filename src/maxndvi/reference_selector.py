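"""Automatic selection of the annual reference NDVI image.

The reference image is meant to capture vegetation at its annual peak: among
a small set of designated *selectable scenes*, candidates with more than the
cloud-fraction threshold (default 40%) of flagged pixels over the ROI are
rejected, and the surviving image with the highest mean NDVI wins.  Ties
break deterministically by earlier acquisition date, then scene notation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NoReferenceError, NoValidPixelsError
from .ndvi_engine import NdviImage, QaScheme
from .raster_scene import RegionOfInterest, SceneID, SRImage, scene_notation


@dataclass(frozen=True)
class SelectionPolicy:
    """Which scenes may supply the reference, and the rejection threshold.

    ``max_cloud_fraction`` rejects strictly greater fractions ("over 40%"),
    and ``min_roi_coverage`` guards against a tiny cloud-free sliver winning
    the mean-NDVI contest.
    """

    selectable_scenes: tuple[SceneID, ...]
    max_cloud_fraction: float = 0.40
    min_roi_coverage: float = 0.01

    def __post_init__(self) -> None:
        if not self.selectable_scenes:
            raise ValueError("selectable_scenes must be nonempty")
        if not (0 < self.max_cloud_fraction <= 1):
            raise ValueError("max_cloud_fraction must be in (0, 1]")


@dataclass
class SelectionReport:
    """Chosen reference plus the full candidate table for auditability."""

    chosen: NdviImage
    candidates: pd.DataFrame  # scene, date, cloud_fraction, mean_ndvi, rejected_reason, chosen

    def to_csv(self, path) -> None:
        self.candidates.to_csv(path, index=False)


def cloud_fraction(image: SRImage, roi: RegionOfInterest,
                   scheme: QaScheme = QaScheme()) -> float:
    """Fraction of observed ROI pixels flagged cloud or cloud shadow.

    Observed means non-fill: the denominator excludes pixels with no
    acquisition at all, so a partial footprint is not penalized.
    """
    roi_mask = roi.raster_mask(image.grid)
    observed = roi_mask & ~scheme.fill(image.qa) & ~_never_observed(image)
    n_obs = int(observed.sum())
    if n_obs == 0:
        raise NoValidPixelsError("no observed pixels in image∩ROI; cloud fraction undefined")
    flagged = scheme.flagged(image.qa) & observed
    return float(flagged.sum()) / n_obs


def _never_observed(image: SRImage) -> np.ndarray:
    # Fill-bit-independent fallback: pixels that were nodata at read time and
    # are not QA-flagged (QA flags fold into nodata after cloud masking).
    return image.nodata_mask & (image.qa == 0)


def mean_ndvi(image: NdviImage, roi: RegionOfInterest) -> float:
    """Arithmetic mean NDVI over valid pixels within the ROI."""
    sel = image.valid_mask & roi.raster_mask(image.grid)
    if not sel.any():
        raise NoValidPixelsError("no valid pixels in image∩ROI; mean undefined")
    return float(image.ndvi[sel].mean())


def select_reference(candidates: list[tuple[SRImage, NdviImage]],
                     policy: SelectionPolicy, roi: RegionOfInterest,
                     scheme: QaScheme = QaScheme()) -> SelectionReport:
    """Pick the reference NDVI image and report every candidate's fate.

    Raises :class:`NoReferenceError` when every candidate is rejected; the
    error message carries the per-candidate reasons.
    """
    rows = []
    survivors: list[tuple[float, object, str, NdviImage]] = []
    roi_mask_cache: dict = {}
    for sr, nd in candidates:
        notation = scene_notation(nd.scene)
        row = {"scene": notation, "date": nd.date, "cloud_fraction": np.nan,
               "mean_ndvi": np.nan, "rejected_reason": "", "chosen": False}
        if nd.scene not in policy.selectable_scenes:
            row["rejected_reason"] = "not a selectable scene"
            rows.append(row)
            continue
        try:
            cf = cloud_fraction(sr, roi, scheme)
        except NoValidPixelsError:
            row["rejected_reason"] = "no observed pixels in ROI"
            rows.append(row)
            continue
        row["cloud_fraction"] = cf
        if nd.grid not in roi_mask_cache:
            roi_mask_cache[nd.grid] = roi.raster_mask(nd.grid)
        roi_mask = roi_mask_cache[nd.grid]
        n_roi = int(roi_mask.sum())
        n_valid = int((nd.valid_mask & roi_mask).sum())
        if cf > policy.max_cloud_fraction:
            row["rejected_reason"] = f"cloud fraction {cf:.2f} over {policy.max_cloud_fraction:.2f}"
            rows.append(row)
            continue
        if n_valid == 0:
            row["rejected_reason"] = "no valid pixels in ROI"
            rows.append(row)
            continue
        if n_roi > 0 and n_valid < policy.min_roi_coverage * n_roi:
            row["rejected_reason"] = f"covers under {policy.min_roi_coverage:.0%} of ROI"
            rows.append(row)
            continue
        mn = float(nd.ndvi[nd.valid_mask & roi_mask].mean())
        row["mean_ndvi"] = mn
        rows.append(row)
        survivors.append((mn, nd.date, notation, nd))

    if not survivors:
        table = pd.DataFrame(rows)
        raise NoReferenceError(
            "all reference candidates rejected:\n" + table.to_string(index=False))

    # Highest mean wins; ties break by earlier date, then scene notation.
    survivors.sort(key=lambda t: (-t[0], t[1], t[2]))
    best_mean, best_date, best_notation, chosen = survivors[0]
    for row in rows:
        if (row["scene"], row["date"]) == (best_notation, best_date):
            row["chosen"] = True
    return SelectionReport(chosen=chosen, candidates=pd.DataFrame(rows))


def rank_scenes_by_roi_overlap(images: list[SRImage],
                               roi: RegionOfInterest) -> pd.DataFrame:
    """Helper for designating selectable scenes: scenes ranked by the map
    area of footprint∩ROI (largest first)."""
    best: dict[SceneID, float] = {}
    for img in images:
        fp = img.footprint_polygon()
        if fp is None:
            continue
        area = fp.intersection(roi.geometry).area
        best[img.scene] = max(best.get(img.scene, 0.0), area)
    rows = [{"scene": scene_notation(s), "roi_overlap_area": a}
            for s, a in sorted(best.items(), key=lambda kv: -kv[1])]
    return pd.DataFrame(rows)
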