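"""Gradient removal and flat-fielding to reflectance."""

import numpy as np
import pytest

from gfuse import (
    BandImage,
    ContractError,
    IlluminationRefs,
    corner_reference,
    gradient_correct,
    illumination_correct,
)


def _img(px, band="green"):
    return BandImage(np.asarray(px, dtype=float), band, "unitless")


# ---------------------------------------------------------------------------
# corner_reference
# ---------------------------------------------------------------------------


class TestCornerReference:
    def test_constant_image_gives_constant_reference(self):
        g = corner_reference(_img(np.full((20, 30), 7.5)), roi_px=4)
        assert np.allclose(g.pixels, 7.5)

    def test_centre_is_mean_of_corner_means(self):
        # top corners 10, bottom corners 20 -> vertical ramp, centre 15
        px = np.zeros((21, 31))
        px[:4, :4] = px[:4, -4:] = 10.0
        px[-4:, :4] = px[-4:, -4:] = 20.0
        g = corner_reference(_img(px), roi_px=4)
        assert g.pixels[10, 15] == pytest.approx(15.0)
        # each corner ROI of the reference averages back to its anchor value
        assert g.pixels[:4, :4].mean() == pytest.approx(10.0)
        assert g.pixels[-4:, -4:].mean() == pytest.approx(20.0)

    def test_bilinear_closed_form_on_arbitrary_corners(self):
        px = np.zeros((11, 11))
        c = {"tl": 2.0, "tr": 6.0, "bl": 10.0, "br": 14.0}
        px[:2, :2], px[:2, -2:] = c["tl"], c["tr"]
        px[-2:, :2], px[-2:, -2:] = c["bl"], c["br"]
        g = corner_reference(_img(px), roi_px=2).pixels
        u = v = 0.5  # centre of an 11x11 grid
        want = ((1 - v) * (1 - u) * c["tl"] + (1 - v) * u * c["tr"]
                + v * (1 - u) * c["bl"] + v * u * c["br"])
        assert g[5, 5] == pytest.approx(want)

    def test_nan_in_a_corner_roi_is_excluded_from_the_mean(self):
        px = np.full((20, 20), 5.0)
        px[0, 0] = np.nan
        px[1, 1] = 9.0
        g = corner_reference(_img(px), roi_px=2)
        assert g.pixels[:2, :2].mean() == pytest.approx((5.0 + 5.0 + 9.0) / 3)

    def test_too_small_image_is_rejected(self):
        with pytest.raises(ContractError):
            corner_reference(_img(np.zeros((6, 20))), roi_px=4)


# ---------------------------------------------------------------------------
# gradient_correct
# ---------------------------------------------------------------------------


class TestGradientCorrect:
    def test_uniform_reference_leaves_image_unchanged(self):
        img = _img(np.random.default_rng(0).uniform(0, 100, (15, 15)))
        out = gradient_correct(img, _img(np.full((15, 15), 42.0)))
        assert np.allclose(out.pixels, img.pixels)

    def test_ramp_gradient_is_fully_removed(self):
        ramp = np.tile(np.linspace(0.0, 20.0, 30), (20, 1))
        base = np.full((20, 30), 50.0)
        out = gradient_correct(_img(base + ramp), _img(ramp + 5.0))
        # a perfect match flattens the image at its left-edge value
        assert np.allclose(out.pixels, 50.0)

    def test_image_is_untouched_at_the_reference_argmin(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 10, (12, 16))
        gref = rng.uniform(5, 9, (12, 16))
        gref[-1, -1] = 1.0  # unique minimum at bottom-right
        out = gradient_correct(_img(img), _img(gref))
        assert out.pixels[-1, -1] == pytest.approx(img[-1, -1])

    def test_grid_mismatch_is_rejected(self):
        with pytest.raises(ContractError):
            gradient_correct(_img(np.zeros((5, 5))), _img(np.zeros((6, 5))))

    def test_corrected_corner_means_agree_with_the_flattest_corner(self):
        rng = np.random.default_rng(2)
        base = np.full((40, 60), 80.0)
        gradient = np.linspace(0, 25, 60)[None, :] + np.linspace(0, 10, 40)[:, None]
        img = _img(base + gradient)
        gref = corner_reference(img, roi_px=4)
        out = gradient_correct(img, gref)
        roi = 4
        corners = [out.pixels[:roi, :roi], out.pixels[:roi, -roi:],
                   out.pixels[-roi:, :roi], out.pixels[-roi:, -roi:]]
        means = [c.mean() for c in corners]
        assert max(means) - min(means) < 1e-6


# ---------------------------------------------------------------------------
# illumination_correct
# ---------------------------------------------------------------------------


class TestIlluminationCorrect:
    def test_backdrop_maps_to_reference_reflectance(self):
        g_cor = _img(np.full((20, 20), 200.0))
        refs = IlluminationRefs(dark=None, ref_factor=0.80)
        out = illumination_correct(g_cor, refs)
        assert out.units == "reflectance"
        assert np.allclose(out.pixels, 0.80)

    def test_dark_level_maps_to_zero(self):
        dark = _img(np.full((20, 20), 5.0))
        px = np.full((20, 20), 180.0)
        px[8:12, 8:12] = 5.0  # a dark patch away from the corners
        out = illumination_correct(_img(px), IlluminationRefs(dark=dark))
        assert np.allclose(out.pixels[8:12, 8:12], 0.0)

    def test_halfway_between_dark_and_white_gives_half_reference(self):
        dark = _img(np.zeros((20, 20)))
        px = np.full((20, 20), 200.0)
        px[9, 9] = 100.0
        out = illumination_correct(_img(px), IlluminationRefs(dark=dark))
        assert out.pixels[9, 9] == pytest.approx(0.40)

    def test_white_equal_dark_becomes_nodata(self):
        dark = _img(np.full((20, 20), 50.0))
        out = illumination_correct(_img(np.full((20, 20), 50.0)),
                                   IlluminationRefs(dark=dark))
        assert np.isnan(out.pixels).all()

    def test_invariant_to_common_positive_gain(self):
        rng = np.random.default_rng(3)
        px = np.full((24, 24), 150.0)
        px[10:14, 10:14] = rng.uniform(30, 120, (4, 4))
        refs = IlluminationRefs(dark=None)
        a = illumination_correct(_img(px), refs)
        b = illumination_correct(_img(px * 3.7), refs)
        assert np.allclose(a.pixels, b.pixels, atol=1e-12)


def test_full_chain_recovers_true_reflectance_within_two_percent(dark_refs):
    """Gradient + dark offset + flat-field chain on a synthetic scene."""
    from gfuse.segmentation import _correct_band
    from gfuse.synthetic import make_plant_capture

    cap, truth = make_plant_capture(seed=3)
    for band in ("nir", "red", "green", "red_edge"):
        out = _correct_band(getattr(cap, band).as_float(), dark_refs)
        err = out.pixels - truth.true_reflectance[band]
        assert np.sqrt(np.nanmean(err ** 2)) < 0.02
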