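# Methods

This note records the model behind `maxndvi`, the parameters that matter,
what the synthetic-scene generator does and does not emulate, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite does not itself compute.

## Pipeline model and assumptions

The composite estimates, per pixel, the annual maximum of
NDVI = (NIR − RED)/(NIR + RED) over a region covered by several
overlapping acquisition footprints ("scenes", identified by path/row and
written `ppprrr`). The chain is

    filter → QA mask → NDVI → reference selection → CDF calibration → median fusion

and rests on two assumptions:

1. **A peak-season reference exists.** At least one selectable-scene
   acquisition near the seasonal peak has acceptable cloud cover (≤ 40 %
   over the ROI). Its value distribution defines the target radiometry.
2. **Distributional similarity of nearby scenes.** Contemporaneous images
   of nearby areas have similar NDVI cumulative distributions, so matching
   a to-be-calibrated image's CDF to the reference's corrects both the
   seasonal amplitude deficit and scene-to-scene tone differences. This is
   a first-law-of-geography argument: it degrades as land-cover composition
   diverges between footprints, which is also why reconstruction error
   grows with the path/row distance from the reference.

Calibration is *distribution* alignment, not regression on shared pixels:
no overlap-region fit, no land-cover stratification, no spatial feathering.
Each image's monotone map preserves its internal pixel ranking; the fused
median then estimates the peak-season value, not the temporal maximum of
raw values (a raw per-pixel max is available as a diagnostic only).

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| month window | Apr–Oct | months, inclusive | vigorous-growth period; Jan–Dec variant for regions where clouds force an all-year window |
| cloud threshold | 0.40 | fraction of observed ROI pixels | candidates *over* 40 % cloud+shadow are rejected (strict inequality) |
| selection statistic | mean NDVI | — | highest mean over valid ROI pixels = closest to peak growth |
| tie-break | earlier date, then scene notation | — | determinism |
| minimum ROI coverage | 0.01 | fraction | guards against a cloud-free sliver winning the mean contest |
| histogram bin width | 0.001 | NDVI | mirrors the conventional ×1000 integer NDVI encoding; configurable |
| QA bits | cloud 3, shadow 4, fill 0 | bit positions | Collection-2 `QA_PIXEL`; dilated-cloud/cirrus rejectable via `extra_bits`, off by default |
| reflectance scaling | gain 2.75e-5, offset −0.2 | — | Collection-2 Level-2 DN convention; overridable per dataset |
| RMSE formula | `standard` | — | see "Numerical choices" |

## The quantile-matching fit

The CDF of each image is a histogram over [−1, 1] with the configured bin
width, computed over valid (cloud-free, observed) pixels inside the ROI.
The calibration map is built from the **mass-centred** discrete quantile
function: each occupied bin contributes (bin centre, cumulative probability
− half the bin's mass). Pairing centres with mid-bin probabilities is the
unbiased discretization of the empirical quantile function; with upper
edges instead, the fitted map carries a systematic half-bin offset on each
side and can disagree with exact empirical quantile matching by more than
one bin width. Targets are obtained by linear interpolation of the
reference quantile function at the source probabilities, forced monotone by
a running maximum, applied by piecewise-linear interpolation between knots,
clamped to the end values outside the support, and clipped to [−1, 1].

A regression-tree backend (`method="cart"`, scikit-learn
`DecisionTreeRegressor` fit on the same matched pairs) is provided behind
the identical interface for fidelity comparisons with tree-based platforms;
the direct quantile map is the default because it *is* the stated objective
(equal cumulative probabilities) with one fewer approximation layer.

Properties, verified by tests: fitted maps are monotone; self-calibration
is the identity to within one bin width; calibrated images match the
reference CDF with sup-distance ≤ 2 bin widths at ≥ 10⁴ pixels; ranking is
preserved. Exact per-pixel idempotence does **not** hold in sparse
distribution tails (the empirical quantile function is steep across support
gaps), so recalibration is tested to move ≤ 1 bin width at the 99.5th
percentile of pixels with a < 0.5 % exception rate.

## Validation protocols

*Leave-one-scene-out:* the acquisition of a nearby scene sharing the
reference date is the "true" image; it is removed (exact scene + date match
only), the pipeline reconstructs the composite, and RMSE is computed over
co-valid ROI pixels. The per-scene applicability report holds out, for
every non-reference scene, its acquisition closest in time to the reference
(absolute day difference, ties to the earlier image) and tabulates
(scene, image distance, n, RMSE).

*Month-by-month:* with the true image removed, each month's image(s) of the
held-out scene are calibrated against the reference — median-fused within
the month when there are several — and scored against the true image.
Months without images report a null RMSE rather than disappearing.

*RMSE formula:* one common typesetting of the formula places 1/n outside
the radical. At realistic pixel counts that variant is orders of magnitude
smaller than the accuracy values actually reported alongside it, so the
default here is the standard √(Σd²/n); the literal variant stays selectable
(`formula="as_printed"`) for transparency and scales as 1/√n.

## The synthetic-scene generator

`simulate_collection` emulates the statistical structure the algorithm
relies on, with known ground truth:

- **Geometry:** rectangular footprints on a path/row grid (same path →
  same acquisition days; +7 days per path step), 35 % overlap, on a shared
  union grid. Default: scenes 125034/125035 (selectable) and 126034,
  192 px edge at 30 m.
- **Latent field:** low-pass-filtered Gaussian noise rank-mapped onto three
  land-cover classes (levels 0.2/0.55/0.9, proportions 0.30/0.45/0.25) plus
  smooth within-class variation — giving the multimodal NDVI histograms
  that exercise CDF matching nontrivially. Correlation length 1 px
  (vegetation patches of 2–3 px ≈ 60–90 m at 30 m resolution). This scale
  is deliberate: what governs calibration accuracy is the number of
  independent field patches per footprint (it sets how similar two
  overlapping footprints' distributions are), and a short correlation
  length keeps that number representative of full-size scenes while the
  raster stays desk-sized.
- **Phenology:** latent NDVI = baseline + amplitude · season(doy) ·
  greenness with a Gaussian season (peak DOY 213, σ 55 d, baseline 0.15,
  amplitude 0.55), so the latent annual maximum is known exactly.
- **Radiometry:** NDVI inverts to (red, nir) with fixed nir + red = 0.6;
  per-acquisition monotone tone distortions r → clip(gain·r^γ + offset)
  with gain ∈ [0.9, 1.1], γ ∈ [0.85, 1.2], offset ∈ [0, 0.05] act in
  reflectance space on non-selectable scenes. Selectable (reference)
  scenes carry identity tone: the latent truth is expressed in the
  reference radiometry, without which "ground-truth recovery" would be
  ill-posed (the composite can only be as accurate as the reference's own
  radiometry).
- **Clouds:** cloud and shadow masks are carved by thresholding a smoothed
  Gaussian field at the target-fraction quantile (8 px blob scale —
  clouds are km-scale objects). This gives spatially coherent masks with
  exact fraction control; it replaces a dilation-growth scheme with a
  simpler, fully vectorized equivalent.
- **Noise:** additive N(0, 0.01) in NDVI units before band inversion.
  Everything is deterministic given the seed.

**What it does not emulate:** orbital geometry beyond rectangular offsets,
radiative transfer, band-specific atmospheric residuals, true land-cover
maps, inter-annual change, or geolocation error. Passing tests therefore
demonstrate that the algorithm removes monotone tone differences and
seasonal amplitude deficits under realistic cloud and noise statistics —
not that it handles non-monotone radiometric effects or strong land-cover
divergence between footprints, which are its documented failure modes.

## Experiment designs used by the acceptance suite

- *Ground-truth recovery* runs the full default conditions (distortions,
  10–40 % clouds, noise) over ten seeds and requires composite RMSE against
  the latent annual maximum below noise sd + 2 bin widths, always beating
  the calibration-off variant.
- *Seamlessness* runs noise- and cloud-free with an explicit γ = 1.35 tone
  on scene 126034 (verified to inject ≥ 0.05 NDVI), so the seam statistic
  isolates tone discontinuity rather than sensor noise. The seam step is
  measured as |Δcomposite − Δtruth| across boundary-straddling pixel pairs
  — the artificial discontinuity in excess of the natural field gradient,
  the only definition under which a perfect composite scores zero on a
  non-constant field.
- *Month-by-month* uses one mid-month acquisition per month plus the
  reference-date acquisition and a sharper season (σ 35 d), clouds off —
  one image per monthly cell isolates the imaging-time effect from the
  image-count effect, mirroring how the experiment is framed.

Problem sizes (192 px scenes, 3 scenes × 13 dates) are the package's
scaled-down study conditions; all statistics that matter (cloud fractions,
distortion ranges, noise, patches per footprint) are kept in their
realistic regimes.

## Known limitations

- Calibration assumes monotone tone differences; non-monotone sensor
  effects (saturation reversal, BRDF hot-spots) are outside the model.
- Distribution matching transfers the *reference's* radiometry; any bias in
  the reference propagates to the whole composite.
- Off-peak images contribute noise amplified by the inverse seasonal
  amplitude ratio; the median bounds, but does not eliminate, their
  influence (visible as the U-shaped month-by-month RMSE profile).
- All multi-image operations require identical grids; reprojection is out
  of scope (a nearest-neighbour re-gridding utility exists for aligning
  synthetic fixtures only).
- Footprint–ROI intersection tests use footprint bounding rectangles, and
  per-image statistics are computed over image∩ROI — partial coverage is
  handled, but no mosaicking across years or regions is attempted.
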