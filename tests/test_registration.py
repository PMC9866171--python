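"""Transform algebra, MSAC, mutual information, warping, fine registration."""

import numpy as np
import pytest
from scipy import ndimage

from gfuse import (
    BandImage,
    ContractError,
    DetectionError,
    FeatureMatchSet,
    RegistrationError,
    Transform2D,
    compose,
    detect_target_corners,
    estimate_coarse,
    fine_register,
    mattes_mmi,
    warp,
)
from gfuse.registration import match_corners
from gfuse.synthetic import make_registration_target

CORNERS = np.array([[0.0, 0.0], [159.0, 0.0], [0.0, 119.0], [159.0, 119.0]])


def _smooth_image(seed=1, shape=(120, 160), sigma=4):
    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.uniform(0, 1, shape), sigma)
    return BandImage((img - img.min()) / (img.max() - img.min()), "nir")


# ---------------------------------------------------------------------------
# compose / Transform2D
# ---------------------------------------------------------------------------


class TestCompose:
    def test_identity_components_give_identity_matrix(self):
        assert np.allclose(compose().matrix, np.eye(3))

    def test_pure_translation_moves_the_origin(self):
        assert compose(tx=5.0).apply([[0.0, 0.0]])[0] == pytest.approx([5.0, 0.0])

    def test_quarter_turn_maps_x_axis_to_y_axis(self):
        t = compose(q=np.pi / 2)
        assert t.apply([[1.0, 0.0]])[0] == pytest.approx([0.0, 1.0], abs=1e-12)

    def test_zero_scale_is_rejected(self):
        with pytest.raises(ContractError):
            compose(sx=0.0)

    def test_composition_is_matrix_product(self):
        a = compose(tx=2, ty=-1, q=0.3)
        b = compose(shx=0.1, sx=1.2, sy=0.9)
        pts = np.array([[1.0, 2.0], [-3.0, 4.0]])
        assert np.allclose((b @ a).apply(pts), b.apply(a.apply(pts)))
        assert np.allclose((b @ a).matrix, b.matrix @ a.matrix)

    def test_rigid_kind_requires_rotation_block(self):
        with pytest.raises(ContractError):
            Transform2D(np.diag([2.0, 1.0, 1.0]), "rigid")
        with pytest.raises(ContractError):
            Transform2D(np.array([[1, 0, 0], [0, 1, 0], [0.1, 0, 1.0]]))


# ---------------------------------------------------------------------------
# Target corner detection
# ---------------------------------------------------------------------------


class TestTargetCorners:
    def test_square_corners_found_within_a_pixel(self):
        img = np.full((120, 160), 30.0)
        img[40:80, 60:100] = 220.0
        img = ndimage.gaussian_filter(img, 1.0)
        pts = detect_target_corners(BandImage(img, "green_rgb"))
        truth = np.array([[60, 40], [99, 40], [60, 79], [99, 79]], dtype=float)
        for t in truth:
            assert np.linalg.norm(pts - t, axis=1).min() < 1.0

    def test_constant_image_raises_detection_error(self):
        with pytest.raises(DetectionError):
            detect_target_corners(BandImage(np.zeros((60, 60)), "thermal"))

    def test_thermal_and_optical_renders_agree(self):
        t = compose(tx=2.0, ty=-1.0, sx=2.0, sy=2.0)
        rgb, thermal, fpts, mpts = make_registration_target(t, seed=2)
        fk = detect_target_corners(rgb)
        mk = detect_target_corners(thermal)
        # every true corner is found in both modalities within a pixel
        for truth, found in ((fpts, fk), (mpts, mk)):
            d = np.linalg.norm(found[:, None] - truth[None], axis=2).min(axis=0)
            assert d.max() < 1.0


# ---------------------------------------------------------------------------
# MSAC coarse estimation
# ---------------------------------------------------------------------------


class TestEstimateCoarse:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.src = rng.uniform(0, 200, (10, 2))
        self.t_true = compose(tx=12.3, ty=-4.5, q=0.15)
        self.dst = self.t_true.apply(self.src)

    def test_exact_correspondences_recover_the_transform(self):
        m = FeatureMatchSet(self.dst, self.src)
        t = estimate_coarse(m)
        assert np.abs(t.matrix - self.t_true.matrix).max() < 1e-6

    def test_gross_outliers_are_flagged_and_ignored(self):
        dst = self.dst.copy()
        dst[[2, 5, 8]] += 30.0
        m = FeatureMatchSet(dst, self.src)
        t = estimate_coarse(m)
        assert not m.inlier_mask[[2, 5, 8]].any()
        assert m.inlier_mask.sum() == 7
        assert np.abs(t.matrix - self.t_true.matrix).max() < 1e-3

    def test_single_pair_is_a_contract_error(self):
        with pytest.raises(ContractError):
            estimate_coarse(FeatureMatchSet(self.dst[:1], self.src[:1]))

    def test_all_outliers_give_no_consensus(self):
        rng = np.random.default_rng(3)
        m = FeatureMatchSet(rng.uniform(0, 200, (12, 2)),
                            rng.uniform(0, 200, (12, 2)))
        with pytest.raises(RegistrationError):
            estimate_coarse(m, msac_threshold_px=0.5)

    def test_similarity_kind_recovers_scale(self):
        t_true = compose(tx=3.0, ty=1.0, q=0.1, sx=1.8, sy=1.8)
        dst = t_true.apply(self.src)
        t = estimate_coarse(FeatureMatchSet(dst, self.src), kind="similarity")
        assert np.abs(t.matrix - t_true.matrix).max() < 1e-6


def test_match_corners_pairs_across_frames_of_different_scale():
    t = compose(tx=3.0, ty=-2.0, sx=2.0, sy=2.0)
    rgb, thermal, fpts, mpts = make_registration_target(t, seed=0)
    m = match_corners(detect_target_corners(rgb), detect_target_corners(thermal))
    assert len(m) >= 8
    est = estimate_coarse(m, kind="similarity")
    residual = np.linalg.norm(est.apply(mpts) - fpts, axis=1)
    assert residual.max() < 1.0


# ---------------------------------------------------------------------------
# Mattes mutual information
# ---------------------------------------------------------------------------


class TestMattesMMI:
    def test_self_information_equals_binned_entropy(self):
        rng = np.random.default_rng(0)
        a = BandImage(rng.uniform(0, 1, (256, 256)), "nir")
        hist, _ = np.histogram(a.pixels, bins=32)
        p = hist / hist.sum()
        entropy = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert mattes_mmi(a, a, bins=32) == pytest.approx(entropy, rel=1e-9)

    def test_independent_noise_has_near_zero_information(self):
        rng = np.random.default_rng(1)
        a = BandImage(rng.uniform(0, 1, (256, 256)), "nir")
        b = BandImage(rng.uniform(0, 1, (256, 256)), "red")
        assert mattes_mmi(a, b, bins=32) < 0.05

    def test_agrees_with_sklearn_contingency_oracle(self):
        from sklearn.metrics import mutual_info_score

        rng = np.random.default_rng(2)
        a = rng.uniform(0, 1, (64, 64))
        b = np.sqrt(a) + 0.05 * rng.standard_normal(a.shape)
        bins = 16

        def digitize(x):
            edges = np.linspace(x.min(), x.max(), bins + 1)
            return np.clip(np.digitize(x, edges[1:-1]), 0, bins - 1)

        oracle = mutual_info_score(digitize(a).ravel(), digitize(b).ravel()) / np.log(2)
        ours = mattes_mmi(BandImage(a, "nir"), BandImage(b, "red"), bins=bins)
        assert ours == pytest.approx(oracle, rel=1e-6)

    def test_invariant_to_gentle_monotone_remapping(self):
        rng = np.random.default_rng(3)
        a = BandImage(rng.uniform(0, 1, (128, 128)), "nir")
        b = BandImage(0.2 + 0.5 * a.pixels, "red")  # affine: bins map 1-1
        assert mattes_mmi(a, b, 32) == pytest.approx(mattes_mmi(a, a, 32), rel=1e-6)

    def test_defined_pixels_only_and_contract_errors(self):
        a = BandImage(np.r_[np.full(50, np.nan), np.arange(50.0)].reshape(10, 10), "nir")
        b = BandImage(np.arange(100.0).reshape(10, 10), "red")
        full = mattes_mmi(a, b, bins=4)
        assert np.isfinite(full)
        disjoint = BandImage(np.r_[np.arange(50.0), np.full(50, np.nan)].reshape(10, 10), "red")
        with pytest.raises(ContractError):
            mattes_mmi(a, disjoint, bins=4)
        with pytest.raises(ContractError):
            mattes_mmi(a, BandImage(np.zeros((5, 5)), "red"), bins=4)  # grid mismatch


# ---------------------------------------------------------------------------
# Warp
# ---------------------------------------------------------------------------


class TestWarp:
    def test_identity_leaves_image_unchanged(self):
        img = _smooth_image()
        out = warp(img, Transform2D.identity(), (160, 120))
        assert np.nanmax(np.abs(out.pixels - img.pixels)) < 1e-12

    def test_translation_of_constant_image_leaves_nodata_margin(self):
        img = BandImage(np.full((50, 60), 7.0), "nir")
        out = warp(img, compose(tx=10.0), (60, 50))
        assert np.isnan(out.pixels[:, :10]).all()
        assert (out.pixels[:, 10:] == 7.0).all()

    def test_round_trip_error_below_one_percent_of_range(self):
        img = _smooth_image(seed=4)
        t = compose(tx=3.2, ty=-1.7, q=0.05)
        back = warp(warp(img, t, (160, 120)), t.inverse(), (160, 120))
        both = np.isfinite(back.pixels)
        rms = np.sqrt(np.mean((back.pixels[both] - img.pixels[both]) ** 2))
        assert rms < 0.01 * np.ptp(img.pixels)

    def test_singular_matrix_is_rejected(self):
        m = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 0.0], [0, 0, 1.0]])
        with pytest.raises(ContractError):
            warp(_smooth_image(), Transform2D(m), (10, 10))


# ---------------------------------------------------------------------------
# Fine registration
# ---------------------------------------------------------------------------


class TestFineRegister:
    def test_known_shift_recovered_within_half_pixel(self):
        fixed = _smooth_image(seed=1)
        t_true = compose(tx=3.0, ty=-2.0)
        moving = warp(fixed, t_true.inverse(), (160, 120))
        t = fine_register(fixed, moving, Transform2D.identity())
        err = np.linalg.norm(t.apply(CORNERS) - t_true.apply(CORNERS), axis=1)
        assert err.max() < 0.5

    def test_identical_images_stay_at_identity(self):
        fixed = _smooth_image(seed=2)
        t = fine_register(fixed, fixed, Transform2D.identity())
        err = np.linalg.norm(t.apply(CORNERS) - CORNERS, axis=1)
        assert err.max() < 0.5

    def test_intensity_inversion_does_not_break_alignment(self):
        fixed = _smooth_image(seed=3)
        t_true = compose(tx=3.0, ty=-2.0)
        moving = warp(fixed, t_true.inverse(), (160, 120))
        inverted = BandImage(1.0 - moving.pixels, "red")
        t = fine_register(fixed, inverted, Transform2D.identity())
        err = np.linalg.norm(t.apply(CORNERS) - t_true.apply(CORNERS), axis=1)
        assert err.max() < 1.0

    def test_result_never_scores_below_the_initialisation(self):
        fixed = _smooth_image(seed=5)
        t_true = compose(tx=2.0, ty=1.0)
        moving = warp(fixed, t_true.inverse(), (160, 120))
        init = Transform2D.identity()
        t = fine_register(fixed, moving, init, max_iterations=50)
        moved_init = warp(moving, init, (160, 120))
        moved_fine = warp(moving, t, (160, 120))

        def overlap_mmi(moved):
            both = np.isfinite(moved.pixels) & np.isfinite(fixed.pixels)
            f = BandImage(np.where(both, fixed.pixels, np.nan), "nir")
            m = BandImage(np.where(both, moved.pixels, np.nan), "red")
            return mattes_mmi(f, m, 64)

        assert overlap_mmi(moved_fine) >= overlap_mmi(moved_init) - 1e-9

    def test_seeded_runs_are_reproducible(self):
        fixed = _smooth_image(seed=6)
        moving = warp(fixed, compose(tx=1.5).inverse(), (160, 120))
        a = fine_register(fixed, moving, Transform2D.identity(), seed=7)
        b = fine_register(fixed, moving, Transform2D.identity(), seed=7)
        assert np.array_equal(a.matrix, b.matrix)

    def test_non_overlapping_init_is_a_registration_error(self):
        fixed = _smooth_image(seed=7)
        with pytest.raises(RegistrationError):
            fine_register(fixed, fixed, compose(tx=500.0))
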