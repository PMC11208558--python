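"""CDF computation, quantile-matching fits, and collection calibration."""

import datetime as dt
import logging

import numpy as np
import pytest
from shapely.geometry import box

from maxndvi import (NoValidPixelsError, RegionOfInterest, SceneID,
                     apply_mapping, calibrate_collection, cdf_of_values,
                     compute_cdf, fit_mapping)
from maxndvi.cdf_calibration import CalibrationMapping

from conftest import make_grid, make_ndvi

BW = 0.001
RNG = np.random.default_rng(42)


def _roi(grid):
    a, _, c, _, e, f = grid.transform
    return RegionOfInterest(box(c, f + grid.height * e, c + grid.width * a, f))


def _sample(n, loc=0.45, scale=0.12, rng=RNG):
    return np.clip(rng.normal(loc, scale, n), -0.98, 0.98)


def _image_of(values):
    side = int(np.sqrt(values.size))
    values = values[: side * side].reshape(side, side).astype(np.float32)
    return make_ndvi(values)


class TestComputeCdf:
    def test_counting_oracle_on_four_pixels(self):
        values = np.array([0.1, 0.1, 0.2, 0.3])
        cdf = cdf_of_values(values, bin_width=0.1)
        # Brute-force oracle: P(X <= upper edge of the bin holding v).
        def cum_at(v):
            k = np.digitize(v, cdf.bin_edges) - 1
            return cdf.cum_prob[k]
        assert cum_at(0.1) == pytest.approx(0.5)
        assert cum_at(0.2) == pytest.approx(0.75)
        assert cum_at(0.3) == pytest.approx(1.0)
        # Full-array check against a per-bin counting loop.
        counts = [np.sum((values >= lo) & (values < hi))
                  for lo, hi in zip(cdf.bin_edges[:-1], cdf.bin_edges[1:])]
        assert np.allclose(cdf.cum_prob, np.cumsum(counts) / values.size)

    def test_constant_image_single_step(self):
        cdf = cdf_of_values(np.full(50, 0.42), bin_width=BW)
        occupied = cdf.occupied()
        assert occupied.sum() == 1
        assert cdf.cum_prob[-1] == 1.0

    def test_final_probability_always_one(self):
        for _ in range(5):
            cdf = cdf_of_values(_sample(1000), bin_width=BW)
            assert cdf.cum_prob[-1] == 1.0
            assert (np.diff(cdf.cum_prob) >= 0).all()

    def test_roi_and_mask_respected(self):
        values = np.array([[0.2, 0.8], [0.4, 0.6]], dtype=np.float32)
        valid = np.array([[True, False], [True, True]])
        img = make_ndvi(values, valid=valid)
        cdf = compute_cdf(img, _roi(img.grid), bin_width=0.1)
        assert cdf.n_pixels == 3

    def test_empty_distribution_is_an_error(self):
        img = make_ndvi(np.zeros((2, 2), np.float32), valid=np.zeros((2, 2), bool))
        with pytest.raises(NoValidPixelsError):
            compute_cdf(img, _roi(img.grid))


class TestFitMapping:
    def test_self_calibration_is_identity_within_one_bin(self):
        cdf = cdf_of_values(_sample(20000), bin_width=BW)
        mapping = fit_mapping(cdf, cdf)
        assert np.max(np.abs(mapping.target_values - mapping.source_values)) <= BW + 1e-12

    def test_shift_recovered(self):
        # Source = reference + 0.1; the map should subtract 0.1 in the interior.
        rng = np.random.default_rng(3)
        ref_vals = _sample(50000, rng=rng)
        src_vals = _sample(50000, rng=rng) + 0.1
        mapping = fit_mapping(cdf_of_values(src_vals, BW), cdf_of_values(ref_vals, BW))
        probes = np.linspace(0.3, 0.7, 21)  # interior of the shifted support
        assert np.max(np.abs(mapping(probes) - (probes - 0.1))) < 0.01

    def test_monotone_distortion_inverted(self):
        # Source = g(reference) for strictly increasing g; fit recovers g^-1.
        def g(v):
            return 0.1 + 0.75 * v + 0.1 * np.sin(2.5 * v)   # g' >= 0.5 on [-1,1]
        rng = np.random.default_rng(4)
        ref_vals = _sample(100000, rng=rng)
        src_vals = g(_sample(100000, rng=rng))
        mapping = fit_mapping(cdf_of_values(src_vals, BW), cdf_of_values(ref_vals, BW))
        probes = np.linspace(0.25, 0.65, 41)
        assert np.max(np.abs(mapping(g(probes)) - probes)) < 0.01

    def test_mapping_is_monotone_for_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = cdf_of_values(_sample(3000, loc=rng.uniform(0.2, 0.6),
                                      scale=rng.uniform(0.05, 0.2), rng=rng), BW)
            b = cdf_of_values(_sample(3000, loc=rng.uniform(0.2, 0.6),
                                      scale=rng.uniform(0.05, 0.2), rng=rng), BW)
            mapping = fit_mapping(a, b)
            assert (np.diff(mapping.target_values) >= 0).all()
            assert mapping.target_values.min() >= -1 and mapping.target_values.max() <= 1

    def test_degenerate_reference_constant_map_with_warning(self):
        src = cdf_of_values(_sample(1000), BW)
        ref = cdf_of_values(np.full(100, 0.3), BW)
        with pytest.warns(UserWarning, match="degenerate"):
            mapping = fit_mapping(src, ref)
        assert np.allclose(mapping.target_values, mapping.target_values[0])

    def test_cart_backend_approximates_quantile_map(self):
        src = cdf_of_values(_sample(20000), BW)
        ref = cdf_of_values(_sample(20000, loc=0.55), BW)
        quantile = fit_mapping(src, ref, method="quantile")
        cart = fit_mapping(src, ref, method="cart")
        assert cart.method_tag == "cart"
        probes = np.linspace(0.2, 0.7, 50)
        assert np.max(np.abs(quantile(probes) - cart(probes))) < 5 * BW

    def test_table_roundtrip(self, tmp_path):
        mapping = fit_mapping(cdf_of_values(_sample(5000), BW),
                              cdf_of_values(_sample(5000), BW))
        path = tmp_path / "mapping.txt"
        mapping.save(path)
        back = CalibrationMapping.load(path)
        probes = np.linspace(-0.5, 0.9, 20)
        assert np.allclose(mapping(probes), back(probes), atol=1e-5)


class TestApplyMapping:
    def test_identity_mapping_leaves_image_unchanged(self):
        img = _image_of(_sample(400))
        ident = CalibrationMapping(np.array([-1.0, 1.0]), np.array([-1.0, 1.0]))
        out = apply_mapping(img, ident)
        assert np.allclose(out.ndvi[out.valid_mask], img.ndvi[img.valid_mask], atol=1e-6)

    def test_constant_mapping(self):
        img = _image_of(_sample(400))
        const = CalibrationMapping(np.array([-1.0, 1.0]), np.array([0.25, 0.25]))
        out = apply_mapping(img, const)
        assert np.allclose(out.ndvi[out.valid_mask], 0.25)

    def test_calibrated_cdf_matches_reference(self):
        # Two-sample CDF comparison: sup distance <= 2 bin widths at >= 1e4 px.
        rng = np.random.default_rng(6)
        ref_img = _image_of(_sample(110 * 110, rng=rng))
        src_img = _image_of(np.clip(0.85 * _sample(110 * 110, rng=rng) + 0.08, -1, 1))
        roi = _roi(ref_img.grid)
        mapping = fit_mapping(compute_cdf(src_img, roi, BW), compute_cdf(ref_img, roi, BW))
        out = apply_mapping(src_img, mapping)
        dist = compute_cdf(out, roi, BW).sup_distance(compute_cdf(ref_img, roi, BW))
        assert dist <= 2 * BW

    def test_rank_preservation(self):
        img = _image_of(_sample(2500))
        mapping = fit_mapping(cdf_of_values(img.ndvi[img.valid_mask], BW),
                              cdf_of_values(_sample(2500, loc=0.6), BW))
        out = apply_mapping(img, mapping)
        order = np.argsort(img.ndvi[img.valid_mask], kind="stable")
        assert (np.diff(out.ndvi[out.valid_mask][order]) >= -1e-9).all()

    def test_mask_unchanged(self):
        values = _sample(100).reshape(10, 10).astype(np.float32)
        valid = np.ones((10, 10), bool)
        valid[3:5] = False
        img = make_ndvi(values, valid=valid)
        mapping = CalibrationMapping(np.array([-1.0, 1.0]), np.array([-1.0, 1.0]))
        out = apply_mapping(img, mapping)
        assert np.array_equal(out.valid_mask, valid)
        assert np.isnan(out.ndvi[~valid]).all()

    def test_skimage_histogram_matching_oracle(self):
        # Independent oracle: scikit-image's exact empirical histogram matching.
        from skimage.exposure import match_histograms
        rng = np.random.default_rng(7)
        ref = _sample(120 * 120, rng=rng).reshape(120, 120)
        src = np.clip(0.9 * _sample(120 * 120, rng=rng) - 0.05, -1, 1).reshape(120, 120)
        ref_img = make_ndvi(ref.astype(np.float32))
        src_img = make_ndvi(src.astype(np.float32))
        roi = _roi(ref_img.grid)
        mapping = fit_mapping(compute_cdf(src_img, roi, BW), compute_cdf(ref_img, roi, BW))
        ours = apply_mapping(src_img, mapping).ndvi
        oracle = match_histograms(src, ref)
        assert np.mean(np.abs(ours - oracle)) < 2 * BW
        assert np.max(np.abs(ours - oracle)) < 10 * BW


class TestCalibrateCollection:
    def test_reference_only_collection_roundtrips(self):
        ref = _image_of(_sample(10000))
        result = calibrate_collection([ref], ref, _roi(ref.grid), BW)
        out = result.images[0]
        assert np.max(np.abs(out.ndvi[out.valid_mask] - ref.ndvi[ref.valid_mask])) <= BW

    def test_known_tone_offset_removed(self):
        # Same latent field, one image offset by +0.08: calibration removes it.
        latent = _sample(110 * 110, rng=np.random.default_rng(8))
        ref = _image_of(latent)
        shifted = _image_of(np.clip(latent + 0.08, -1, 1))
        result = calibrate_collection([shifted], ref, _roi(ref.grid), BW)
        out = result.images[0]
        both = out.valid_mask & ref.valid_mask
        assert abs(np.mean(out.ndvi[both] - ref.ndvi[both])) < BW

    def test_idempotence(self):
        # Recalibrating an already-calibrated image is a near no-op.  Exact
        # per-pixel idempotence cannot hold in the sparse distribution tails
        # (empirical quantile maps are steep across support gaps there), so
        # the body of the distribution is held to one bin width and the
        # exceptions are required to be a vanishing fraction.
        rng = np.random.default_rng(9)
        ref = _image_of(_sample(10000, rng=rng))
        src = _image_of(np.clip(1.1 * _sample(10000, rng=rng), -1, 1))
        roi = _roi(ref.grid)
        once = calibrate_collection([src], ref, roi, BW).images[0]
        twice = calibrate_collection([once], ref, roi, BW).images[0]
        change = np.abs(twice.ndvi[twice.valid_mask] - once.ndvi[once.valid_mask])
        assert np.quantile(change, 0.995) <= BW + 1e-9
        assert np.mean(change > BW) < 0.005

    def test_fully_masked_image_dropped_with_warning(self, caplog):
        ref = _image_of(_sample(400))
        dead = make_ndvi(np.zeros((20, 20), np.float32), valid=np.zeros((20, 20), bool),
                         scene=SceneID(126, 34), date=dt.date(2021, 5, 1))
        with caplog.at_level(logging.WARNING, logger="maxndvi.cdf_calibration"):
            result = calibrate_collection([ref, dead, ref], ref, _roi(ref.grid), BW)
        assert len(result.images) == 2
        assert result.dropped == [("126034", dt.date(2021, 5, 1))]
        assert any("no valid pixels" in rec.message for rec in caplog.records)
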