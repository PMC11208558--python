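# maxndvi

Seamless, temporally consistent **annual-maximum NDVI** composites from
multi-scene, multi-date surface-reflectance imagery — plus the validation
harness (leave-one-scene-out RMSE, image distance, month-by-month
calibration accuracy) and a synthetic-scene simulator with known ground
truth.

## The problem

Annual-maximum NDVI, max<sub>t</sub> (NIR−RED)/(NIR+RED), is the standard
proxy for peak vegetation vigour in change monitoring (mining disturbance,
restoration, phenology drift). Building it from Landsat-class imagery is
harder than it sounds: clouds and the 16-day revisit remove exactly the
peak-season acquisitions over part of the area, and naive mosaics mix
scenes acquired weeks apart. The result is a composite with visible **mosaic
lines** at scene boundaries and values biased **below** the true annual
maximum wherever the peak acquisition is missing.

## The method

For one region of interest and one year:

1. **Filter** the collection by month window (default April–October) and
   ROI intersection; **mask** cloud and cloud-shadow pixels via the QA
   bitmask (Collection-2 `QA_PIXEL` bits 3 and 4 by default); compute
   per-image NDVI.
2. **Select the reference image**: among 2–3 designated *selectable
   scenes*, drop candidates with more than 40 % cloud over the ROI, and take
   the image with the highest mean NDVI — the best available snapshot of
   peak growth.
3. **Calibrate** every image to the reference by **CDF (quantile)
   matching**: each value *aᵢ* maps to the reference value *bⱼ* at the same
   cumulative probability (histogram bin width 0.001 NDVI). Nearby,
   contemporaneous scenes have similar value distributions, so this monotone
   map removes both the seasonal amplitude deficit and inter-scene tone
   differences while preserving spatial pattern (pixel ranks).
4. **Fuse** the calibrated stack by the **per-pixel median** (even counts:
   mean of the two central values), which also suppresses anomalous
   residuals such as unscreened cloud.

Validation follows the leave-one-scene-out protocol: the acquisition
sharing the reference date in a nearby scene is withheld as the *true*
image, the pipeline reconstructs it, and accuracy is RMSE over co-valid
pixels. The *image distance* |ΔPath| + |ΔRow| summarizes how far a
calibrated scene sits from the reference on the acquisition grid.

## Worked example

```python
import numpy as np
from maxndvi import (DateWindow, SelectionPolicy, SimulationConfig,
                     composite_annual_max, scene_boundaries, seam_profile,
                     simulate_collection)

config = SimulationConfig(seed=42)        # 3 scenes x 13 dates, clouds, tone distortions
images, truth = simulate_collection(config)
roi = config.roi()
policy = SelectionPolicy(selectable_scenes=config.selectable_scenes)

composite, report = composite_annual_max(images, config.year, DateWindow(4, 10),
                                         roi, policy)
chosen = report.candidates[report.candidates.chosen].iloc[0]
print(f"reference: scene {chosen.scene} on {chosen.date} "
      f"(mean NDVI {chosen.mean_ndvi:.3f}, cloud fraction {chosen.cloud_fraction:.2f})")

observed = ~composite.mask
err = composite.ndvi_max[observed] - truth.latent_max_ndvi[observed]
print(f"composite RMSE vs latent annual maximum: {np.sqrt(np.mean(err**2)):.4f}")

steps = [seam_profile(composite, truth, b)[0] for b in scene_boundaries(truth)]
print(f"mean seam step across scene boundaries: {np.nanmean(steps):.4f}")

raw, _ = composite_annual_max(images, config.year, DateWindow(4, 10), roi,
                              policy, calibration=False)
raw_err = raw.ndvi_max[~raw.mask] - truth.latent_max_ndvi[~raw.mask]
print(f"without calibration the RMSE is {np.sqrt(np.mean(raw_err**2)):.4f}")
```

Output:

```
reference: scene 125034 on 2021-08-01 (mean NDVI 0.439, cloud fraction 0.26)
composite RMSE vs latent annual maximum: 0.0076
mean seam step across scene boundaries: 0.0069
without calibration the RMSE is 0.1294
```

The reference lands on the phenology peak (August 1). The calibrated
composite recovers the latent annual-maximum field to within the simulated
sensor noise (sd 0.01), while the calibration-off variant is ~17× worse
because off-peak, tone-distorted images drag the median down. The residual
seam step here is noise-dominated; with noise switched off it falls below
two histogram bin widths (0.002), i.e. no visible mosaic line.

## Command line

```bash
maxndvi simulate --config sim.yaml --out fixture/     # GeoTIFFs + manifest + ROI
maxndvi composite fixture/ --out out/                 # ndvi_max_YYYY.tif, count_YYYY.tif, selection_YYYY.csv
maxndvi validate fixture/ --mode scene --out val/     # per-scene distance + RMSE table
maxndvi validate fixture/ --mode monthly --out val/   # month-by-month RMSE table
```

Exit codes: 0 success, 2 configuration error, 3 no usable reference /
empty collection, 4 I/O failure.

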