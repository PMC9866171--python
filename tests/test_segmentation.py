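"""Canopy masking, stack assembly, and segmentation quality metrics."""

import logging

import numpy as np
import pytest

from gfuse import (
    BandImage,
    ContractError,
    IlluminationRefs,
    Mask,
    StageError,
    ThermalScale,
    Transform2D,
    apply_mask,
    build_stack,
    plant_mask,
    seg_metrics,
)
from gfuse.raster import STACK_BAND_ORDER
from gfuse.synthetic import DEFAULT_SIZE, make_plant_capture


# ---------------------------------------------------------------------------
# plant_mask
# ---------------------------------------------------------------------------


class TestPlantMask:
    def test_recovers_true_silhouette_with_high_iou(self, default_capture):
        cap, truth = default_capture
        m = plant_mask(cap.rgb)
        t = truth.true_mask.pixels
        iou = (m.pixels & t).sum() / (m.pixels | t).sum()
        assert iou >= 0.95

    def test_all_white_frame_gives_empty_mask_with_warning(self, caplog):
        rgb = BandImage(np.full((60, 80, 3), 255, dtype=np.uint8), "rgb", "dn8")
        with caplog.at_level(logging.WARNING):
            m = plant_mask(rgb)
        assert m.coverage == 0.0
        assert any("empty mask" in r.message for r in caplog.records)

    def test_soft_background_shadow_is_excluded(self):
        cap, truth = make_plant_capture(seed=6)
        px = cap.rgb.pixels.astype(float)
        shadow = ~truth.true_mask.pixels[:, :140]
        px[:, :140][shadow] *= 0.8  # 20% darkening of the backdrop
        shaded = BandImage(np.clip(px, 0, 255).astype(np.uint8), "rgb", "dn8")
        m = plant_mask(shaded)
        t = truth.true_mask.pixels
        iou = (m.pixels & t).sum() / (m.pixels | t).sum()
        assert iou >= 0.9

    def test_even_window_is_rejected(self, default_capture):
        with pytest.raises(ContractError):
            plant_mask(default_capture[0].rgb, window_px=50)


# ---------------------------------------------------------------------------
# apply_mask
# ---------------------------------------------------------------------------


class TestApplyMask:
    def test_all_true_mask_is_identity(self):
        img = BandImage(np.arange(12.0).reshape(3, 4), "nir")
        out = apply_mask(img, Mask(np.ones((3, 4), bool)))
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_all_false_mask_blanks_everything(self):
        img = BandImage(np.arange(12.0).reshape(3, 4), "nir")
        assert np.isnan(apply_mask(img, Mask(np.zeros((3, 4), bool))).pixels).all()

    def test_checkerboard_mask_keeps_exactly_coverage_pixels(self):
        h = w = 16
        mask = Mask(np.indices((h, w)).sum(axis=0) % 2 == 0)
        img = BandImage(np.full((h, w), 3.0), "nir")
        out = apply_mask(img, mask)
        assert np.isfinite(out.pixels).sum() == int(mask.coverage * h * w)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        img = BandImage(rng.uniform(0, 1, (10, 10)), "nir")
        mask = Mask(rng.uniform(size=(10, 10)) > 0.5)
        once = apply_mask(img, mask)
        twice = apply_mask(once, mask)
        np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_grid_mismatch_is_rejected(self):
        with pytest.raises(ContractError):
            apply_mask(BandImage(np.zeros((4, 4)), "nir"), Mask(np.ones((5, 4), bool)))


# ---------------------------------------------------------------------------
# build_stack
# ---------------------------------------------------------------------------


def _scale_for(truth):
    return truth.scale


class TestBuildStack:
    def test_clean_fixture_recovers_temperature_and_reflectance(
        self, clean_capture, dark_refs
    ):
        cap, truth = clean_capture
        stack = build_stack(cap, truth.true_transform, truth.scale, dark_refs,
                            image_area=truth.image_area)
        assert stack.band_names == STACK_BAND_ORDER
        on = stack.mask.pixels
        temp_err = np.abs(stack.band("thermal").pixels - truth.true_temperature.pixels)
        assert np.nanmax(temp_err[on]) <= truth.scale.degrees_per_dn
        for name in ("nir", "red", "green", "red_edge"):
            err = (stack.band(name).pixels - truth.true_reflectance[name])[on]
            assert np.sqrt(np.mean(err ** 2)) < 0.02

    def test_defined_pixels_equal_the_mask_everywhere(self, clean_capture, dark_refs):
        cap, truth = clean_capture
        stack = build_stack(cap, truth.true_transform, truth.scale, dark_refs,
                            image_area=truth.image_area)
        for band in stack.bands:
            np.testing.assert_array_equal(band.defined(), stack.mask.pixels)

    def test_stage_error_names_capture_and_stage(self, clean_capture, dark_refs):
        cap, truth = clean_capture
        bad_scale = ThermalScale(20.0, 30.0, 0, 255)
        broken = BandImage(np.zeros((10, 10)), "thermal", "celsius")  # wrong units
        cap2 = type(cap)(rgb=cap.rgb, green=cap.green, red=cap.red,
                         red_edge=cap.red_edge, nir=cap.nir, thermal=broken,
                         capture_id="bad-thermal")
        with pytest.raises(StageError) as err:
            build_stack(cap2, truth.true_transform, bad_scale, dark_refs)
        assert "thermal-rescale" in str(err.value)
        assert "bad-thermal" in str(err.value)

    def test_empty_mask_gives_all_nodata_stack_not_an_error(self, dark_refs, caplog):
        cap, truth = make_plant_capture(seed=8, thermal_size=DEFAULT_SIZE,
                                        true_transform=Transform2D.identity())
        white = BandImage(np.full(cap.rgb.pixels.shape, 200, dtype=np.uint8),
                          "rgb", "dn8")
        cap2 = type(cap)(rgb=white, green=cap.green, red=cap.red,
                         red_edge=cap.red_edge, nir=cap.nir, thermal=cap.thermal,
                         capture_id="no-plant")
        with caplog.at_level(logging.WARNING):
            stack = build_stack(cap2, truth.true_transform, truth.scale, dark_refs,
                                image_area=truth.image_area)
        assert stack.mask.coverage == 0.0
        assert all(np.isnan(b.pixels).all() for b in stack.bands)


# ---------------------------------------------------------------------------
# seg_metrics
# ---------------------------------------------------------------------------


class TestSegMetrics:
    def test_identical_images_score_perfectly(self):
        rng = np.random.default_rng(0)
        img = BandImage(rng.uniform(0, 1, (64, 64)), "nir")
        rmse, ssim_map = seg_metrics(img, img)
        assert rmse == 0.0
        assert np.allclose(ssim_map.pixels, 1.0)

    def test_opposite_constants_give_unit_rmse(self):
        ones = BandImage(np.ones((32, 32)), "nir")
        zeros = BandImage(np.zeros((32, 32)), "nir")
        rmse, _ = seg_metrics(ones, zeros)
        assert rmse == pytest.approx(1.0)

    def test_rmse_matches_direct_loop_oracle_on_plant_fixture(self, default_capture):
        cap, truth = default_capture
        rgb = BandImage(cap.rgb.pixels, "rgb", "dn8")
        segmented = apply_mask(rgb, truth.true_mask)
        rmse, _ = seg_metrics(rgb, segmented)
        # direct loop over normalised greyscale, background compared to 0
        a = cap.rgb.pixels.astype(float).mean(axis=2) / 255.0
        b = np.where(truth.true_mask.pixels, a, 0.0)
        total = 0.0
        for i in range(a.shape[0]):
            for j in range(a.shape[1]):
                total += (a[i, j] - b[i, j]) ** 2
        want = np.sqrt(total / a.size)
        assert rmse == pytest.approx(want, rel=1e-9)

    def test_grid_mismatch_is_rejected(self):
        with pytest.raises(ContractError):
            seg_metrics(BandImage(np.zeros((4, 4)), "nir"),
                        BandImage(np.zeros((5, 5)), "nir"))
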