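"""Synthetic capture generator: every input the pipeline consumes, with truth.

The generators emulate the glasshouse rig — a thermal camera and a
multispectral camera on a shared mount, a white 80%-reflectance backdrop, a
checkerboard for per-band lens calibration and a corflute cut-out target for
cross-modality registration — as pure functions of a seed, so the whole test
suite runs without hardware or downloads and every claim can be checked
against ground truth.

What is emulated, and how:

* **Checkerboard views** are ray-traced through the full pinhole + radial
  distortion model at random poses; the true image-plane corner positions
  come from the same projection, so calibration can be scored exactly.
* **Registration targets** render the same cut-out geometry twice: dark
  shapes on a light sheet for the optical frame, hot (bright) holes in a
  cool sheet for the thermal frame — corners coincide by construction.
* **Plant captures** compose a leafy rosette silhouette with per-band leaf
  reflectances, a smooth within-canopy shading field (which also drives leaf
  temperature, as transpiration structure does), an additive directional
  illumination gradient that vanishes at its darkest corner, a dark offset,
  and Gaussian sensor noise.  The thermal frame is rendered through the
  inverse radiometric map and carries a scale bar with dot-matrix digit
  labels readable by the bundled OCR.

Defaults follow the real rig scaled down 4x (thermal 160x120, common
multispectral/RGB grid 320x240) to keep tests fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .calibration import CameraModel, CheckerboardSpec
from .raster import BandImage, CaptureSet, ContractError
from .registration import Transform2D, compose
from .segmentation import Mask
from .thermal import OcrRegion, ThermalScale, render_text

__all__ = [
    "SceneTruth",
    "make_checkerboard_views",
    "make_registration_target",
    "make_plant_capture",
    "default_camera",
    "DEFAULT_SIZE",
    "DEFAULT_THERMAL_SIZE",
]

#: common multispectral/RGB grid (width, height): the real rig's 1290x960
#: multispectral frame scaled down by 4
DEFAULT_SIZE = (320, 240)
#: thermal frame (width, height): 640x480 scaled down by 4
DEFAULT_THERMAL_SIZE = (160, 120)

#: leaf reflectance by band (healthy wheat canopy, broadband averages) and
#: the white backdrop's flat 80% reflectance
PLANT_REFLECTANCE = {
    "green": 0.25,
    "red": 0.08,
    "red_edge": 0.45,
    "nir": 0.55,
    "red_rgb": 0.10,
    "green_rgb": 0.30,
    "blue": 0.12,
}
BACKDROP_REFLECTANCE = 0.80

#: forward sensor model: DN = dark + (reflectance / backdrop_reflectance)
#: * illum_level + gradient + noise
DARK_LEVEL_DN = 5.0
ILLUM_LEVEL_DN = 190.0

#: canopy temperatures: transpiring leaves run several degrees cooler than
#: the sun-warmed backdrop
BACKDROP_TEMP_C = 28.0
LEAF_TEMP_RANGE_C = (19.0, 24.0)

#: scale-bar legend geometry on the thermal frame (right margin)
LEGEND_WIDTH_PX = 30


@dataclass
class SceneTruth:
    """Ground truth for one synthetic plant capture."""

    true_mask: Mask
    true_reflectance: dict
    true_temperature: BandImage
    true_transform: Transform2D
    illumination_gradient: np.ndarray
    scale: ThermalScale
    ocr_region: OcrRegion
    image_area: Tuple[int, int, int, int]
    seed: int


# ---------------------------------------------------------------------------
# Camera + checkerboard rendering
# ---------------------------------------------------------------------------


def default_camera(band: str = "nir", size=DEFAULT_SIZE,
                   k1: float = -0.2, k2: float = 0.05, k3: float = 0.0) -> CameraModel:
    """A plausible narrow-band lens for the scaled-down sensor."""
    w, h = size
    return CameraModel(fx=0.95 * w, fy=0.95 * w, cx=(w - 1) / 2.0,
                       cy=(h - 1) / 2.0, k1=k1, k2=k2, k3=k3, band=band)


def _board_pose(rng, model: CameraModel, spec: CheckerboardSpec, size):
    """Sample a pose that keeps all corners inside the frame."""
    w, h = size
    obj = spec.object_points()
    centre = obj.mean(axis=0)
    board_w = spec.inner_cols * spec.square_size_mm
    for _ in range(200):
        rot = Rotation.from_euler(
            "xyz", rng.uniform([-0.25, -0.25, -0.35], [0.25, 0.25, 0.35])
        )
        # close range: the board fills 55-85% of the frame width, as in real
        # calibration practice — off-axis coverage is what identifies the
        # radial coefficients
        z = rng.uniform(0.9, 1.4) * model.fx * board_w / (0.75 * w * spec.square_size_mm) \
            * spec.square_size_mm
        # lateral offsets push the board toward the frame corners on some
        # views, extending the off-axis radius range the fit sees
        jitter = rng.uniform(-0.18, 0.18, size=2) * z
        tvec = -rot.as_matrix() @ centre + np.array([jitter[0], jitter[1], z])
        rvec = rot.as_rotvec()
        pts = model.project(obj, rvec, tvec)
        if (pts[:, 0].min() > 8 and pts[:, 0].max() < w - 9
                and pts[:, 1].min() > 8 and pts[:, 1].max() < h - 9):
            return rvec, tvec, pts
    raise ContractError("could not place the board inside the frame")


def _render_board(model: CameraModel, spec: CheckerboardSpec,
                  rvec, tvec, size, supersample: int = 3) -> np.ndarray:
    """Ray-trace the checkerboard through the distortion model (uint8)."""
    w, h = size
    ss = supersample
    # subpixel sample grid
    off = (np.arange(ss) + 0.5) / ss - 0.5
    R = Rotation.from_rotvec(rvec).as_matrix()
    # homography board(mm) -> ideal normalised image coords
    H = np.column_stack([R[:, 0], R[:, 1], np.asarray(tvec)])
    Hinv = np.linalg.inv(H)
    acc = np.zeros((h, w))
    board_w = spec.squares_cols * spec.square_size_mm
    board_h = spec.squares_rows * spec.square_size_mm
    s = spec.square_size_mm
    for dy in off:
        for dx in off:
            vv, uu = np.mgrid[0:h, 0:w].astype(float)
            xd, yd = model.from_pixels(uu + dx, vv + dy)
            x, y = model.undistort_normalised(xd, yd)
            denom = Hinv[2, 0] * x + Hinv[2, 1] * y + Hinv[2, 2]
            X = (Hinv[0, 0] * x + Hinv[0, 1] * y + Hinv[0, 2]) / denom
            Y = (Hinv[1, 0] * x + Hinv[1, 1] * y + Hinv[1, 2]) / denom
            # the inner-corner origin sits one square in from the board edge
            inside = (X > -s) & (X < board_w - s) & (Y > -s) & (Y < board_h - s)
            parity = (np.floor(X / s) + np.floor(Y / s)) % 2
            shade = np.where(parity == 0, 30.0, 225.0)
            acc += np.where(inside, shade, 160.0)
    img = acc / (ss * ss)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def make_checkerboard_views(
    model: CameraModel,
    spec: CheckerboardSpec,
    n_views: int = 10,
    noise_px: float = 0.0,
    seed: int = 0,
    size=DEFAULT_SIZE,
    render: bool = True,
):
    """Render checkerboard calibration views with known corner truth.

    Returns ``(images, true_corners, noisy_corners)``: per view, the rendered
    frame (or ``None`` when ``render=False``), the exact projected inner
    corners, and the same corners with Gaussian noise of ``noise_px`` added —
    the realistic "detected" input for calibration.
    """
    if n_views < 1:
        raise ContractError("need at least one view")
    rng = np.random.default_rng(seed)
    images, truths, noisy = [], [], []
    for _ in range(n_views):
        rvec, tvec, pts = _board_pose(rng, model, spec, size)
        img = None
        if render:
            img = BandImage(_render_board(model, spec, rvec, tvec, size),
                            model.band, "dn8")
        images.append(img)
        truths.append(pts)
        noisy.append(pts + rng.normal(0.0, noise_px, size=pts.shape)
                     if noise_px > 0 else pts.copy())
    return images, truths, noisy


# ---------------------------------------------------------------------------
# Registration target
# ---------------------------------------------------------------------------

#: cut-out shapes as polygons in unit coordinates (x, y), scaled to the frame
_TARGET_SHAPES = [
    # square
    [(0.15, 0.15), (0.38, 0.15), (0.38, 0.42), (0.15, 0.42)],
    # triangle
    [(0.60, 0.14), (0.87, 0.20), (0.66, 0.44), ],
    # chevron (4 corners visible)
    [(0.18, 0.60), (0.45, 0.58), (0.40, 0.72), (0.22, 0.85)],
    # diamond
    [(0.72, 0.58), (0.86, 0.68), (0.74, 0.86), (0.60, 0.70)],
]


def _raster_polygons(size, shapes, fg: float, bg: float, supersample: int = 4) -> np.ndarray:
    """Anti-aliased polygon raster (supersampled), so corners sit sub-pixel true."""
    from skimage.draw import polygon

    w, h = size
    ss = supersample
    img = np.full((h * ss, w * ss), bg)
    for poly in shapes:
        # pixel-centre convention: scene coordinate p maps to supersample
        # index ss*p + (ss-1)/2
        xs = np.array([p[0] for p in poly]) * w * ss + (ss - 1) / 2.0
        ys = np.array([p[1] for p in poly]) * h * ss + (ss - 1) / 2.0
        rr, cc = polygon(ys, xs, shape=(h * ss, w * ss))
        img[rr, cc] = fg
    return img.reshape(h, ss, w, ss).mean(axis=(1, 3))


def make_registration_target(
    true_transform: Transform2D,
    seed: int = 0,
    size=DEFAULT_SIZE,
    thermal_size=DEFAULT_THERMAL_SIZE,
    noise_sd_dn: float = 1.5,
):
    """Paired optical/thermal renders of the cut-out target, plus truth.

    ``true_transform`` maps thermal coordinates into the fixed optical frame.
    Returns ``(rgb_frame, thermal_frame, fixed_corners, thermal_corners)``
    where the corner lists are corresponding polygon vertices (>= 8 pairs).
    Raises :class:`ContractError` if any shape corner falls outside either
    frame.
    """
    rng = np.random.default_rng(seed)
    w, h = size
    tw, th = thermal_size
    fixed_corners = np.array(
        [(x * w, y * h) for poly in _TARGET_SHAPES for (x, y) in poly]
    )
    inv = true_transform.inverse()
    thermal_corners = inv.apply(fixed_corners)
    if (fixed_corners[:, 0].min() < 0 or fixed_corners[:, 0].max() >= w
            or thermal_corners[:, 0].min() < 2 or thermal_corners[:, 0].max() >= tw - 2
            or thermal_corners[:, 1].min() < 2 or thermal_corners[:, 1].max() >= th - 2):
        raise ContractError("target shapes are clipped by a frame under this transform")

    # optical: dark cut-outs on a light corflute sheet
    rgb_scene = _raster_polygons(size, _TARGET_SHAPES, fg=40.0, bg=215.0)
    rgb_scene += rng.normal(0.0, noise_sd_dn, rgb_scene.shape)
    rgb_frame = BandImage(
        np.clip(np.round(rgb_scene), 0, 255).astype(np.uint8), "green_rgb", "dn8"
    )

    # thermal: the holes expose the warm wall -> bright; sheet is cool
    vv, uu = np.mgrid[0:th, 0:tw].astype(float)
    mapped = true_transform.apply(np.column_stack([uu.ravel(), vv.ravel()]))
    from scipy import ndimage as ndi

    hot_scene = _raster_polygons(size, _TARGET_SHAPES, fg=220.0, bg=60.0)
    sampled = ndi.map_coordinates(
        hot_scene, [mapped[:, 1], mapped[:, 0]], order=1, mode="nearest"
    ).reshape(th, tw)
    sampled += rng.normal(0.0, noise_sd_dn, sampled.shape)
    thermal_frame = BandImage(
        np.clip(np.round(sampled), 0, 255).astype(np.uint8), "thermal", "dn8"
    )
    return rgb_frame, thermal_frame, fixed_corners, thermal_corners


# ---------------------------------------------------------------------------
# Plant capture
# ---------------------------------------------------------------------------


def _leaf_mask(rng, size, n_crowns: int = 5, leaves_per_crown: int = 7) -> np.ndarray:
    """Frontal view of potted wheat: fans of thin curved blades, crisp edges.

    Several crowns spread along the pot line each send up a fan of
    parallel-sided blades with blunt tapering tips — the thin, striated
    structure a frontal glasshouse capture actually shows, and the regime in
    which local-mean thresholding can see background near every leaf.  Blade
    reach is capped so the four corner white-reference ROIs stay on backdrop.
    """
    w, h = size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    mask = np.zeros((h, w), dtype=bool)
    for c in range(n_crowns):
        cx = w * (0.18 + 0.64 * c / max(n_crowns - 1, 1)) + rng.uniform(-10, 10)
        cy = h * 0.85 + rng.uniform(-6, 6)
        for _ in range(leaves_per_crown):
            ang = rng.uniform(np.pi * 1.15, np.pi * 1.85)  # upward fan
            length = rng.uniform(0.45, 0.8) * h
            width = rng.uniform(6.0, 12.0)
            curve = rng.uniform(-0.25, 0.25)
            dx, dy = np.cos(ang), np.sin(ang)
            u = (xx - cx) * dx + (yy - cy) * dy
            v = -(xx - cx) * dy + (yy - cy) * dx + curve * u ** 2 / length
            t = u / length
            prof = np.clip(1.6 * np.sin(np.clip(t, 0, 1) * np.pi), 0, 1)
            mask |= (np.abs(v) <= width / 2.0 * prof) & (t > 0) & (t < 1)
    return mask


def _shading_field(rng, size) -> np.ndarray:
    """Smooth multiplicative within-canopy shading in [0.7, 1.3]."""
    w, h = size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    u, v = xx / w, yy / h
    phases = rng.uniform(0, 2 * np.pi, size=4)
    freq = rng.uniform(1.5, 3.5, size=4)
    f = (np.sin(2 * np.pi * freq[0] * u + phases[0])
         + np.sin(2 * np.pi * freq[1] * v + phases[1])
         + np.sin(2 * np.pi * freq[2] * (u + v) + phases[2])
         + np.sin(2 * np.pi * freq[3] * (u - v) + phases[3]))
    f = (f - f.min()) / max(f.max() - f.min(), 1e-12)
    return 0.7 + 0.6 * f


def _gradient_field(rng, size) -> np.ndarray:
    """Planar directional gradient in [0, 1] with its zero at one corner."""
    w, h = size
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    u, v = xx / (w - 1), yy / (h - 1)
    ax, ay = rng.uniform(-1.0, 1.0, size=2)
    if abs(ax) + abs(ay) < 0.2:
        ax, ay = 1.0, 0.5
    g = ax * u + ay * v
    g -= g.min()
    return g / max(g.max(), 1e-12)


def make_plant_capture(
    seed: int = 0,
    size=DEFAULT_SIZE,
    thermal_size=DEFAULT_THERMAL_SIZE,
    true_transform: Optional[Transform2D] = None,
    n_crowns: int = 5,
    leaves_per_crown: int = 7,
    gradient_amplitude: float = 0.2,
    noise_sd: float = 0.01,
    capture_id: Optional[str] = None,
):
    """Synthesise one full plant capture with ground truth.

    Parameters
    ----------
    true_transform:
        Thermal -> common-grid transform.  Default: the thermal frame covers
        the common grid at half resolution with a small translation offset.
    gradient_amplitude:
        Peak of the additive illumination gradient as a fraction of the
        illumination level.
    noise_sd:
        Gaussian sensor noise on the optical bands, as a fraction of full
        scale (8 bit).  The thermal render's only noise is quantisation.

    Returns ``(CaptureSet, SceneTruth)``.
    """
    rng = np.random.default_rng(seed)
    w, h = size
    tw, th = thermal_size
    if true_transform is None:
        true_transform = compose(tx=rng.uniform(-4, 4), ty=rng.uniform(-3, 3),
                                 sx=w / tw, sy=h / th)

    canopy = _leaf_mask(rng, size, n_crowns, leaves_per_crown)
    shading = _shading_field(rng, size)
    gradient = _gradient_field(rng, size)

    # --- true reflectance fields -----------------------------------------
    true_refl = {}
    for band, rho in PLANT_REFLECTANCE.items():
        r = np.where(canopy, np.clip(rho * shading, 0.0, 0.79), BACKDROP_REFLECTANCE)
        true_refl[band] = r

    # --- true temperature field ------------------------------------------
    t_lo, t_hi = LEAF_TEMP_RANGE_C
    leaf_t = t_lo + (t_hi - t_lo) * (shading - 0.7) / 0.6
    true_temp = np.where(canopy, leaf_t, BACKDROP_TEMP_C)

    # --- optical forward model -------------------------------------------
    amp = gradient_amplitude * ILLUM_LEVEL_DN

    def render_band(refl, band):
        dn = (DARK_LEVEL_DN
              + refl / BACKDROP_REFLECTANCE * ILLUM_LEVEL_DN
              + amp * gradient)
        if noise_sd > 0:
            dn = dn + rng.normal(0.0, noise_sd * 255.0, dn.shape)
        return np.clip(np.round(dn), 0, 255).astype(np.uint8)

    spectral = {b: BandImage(render_band(true_refl[b], b), b, "dn8")
                for b in ("green", "red", "red_edge", "nir")}
    rgb_px = np.dstack([render_band(true_refl[b], b)
                        for b in ("red_rgb", "green_rgb", "blue")])
    rgb = BandImage(rgb_px, "rgb", "dn8")

    # --- thermal forward model -------------------------------------------
    min_t = float(np.floor(true_temp.min() * 10) / 10)
    max_t = float(np.ceil(true_temp.max() * 10) / 10)
    scale = ThermalScale(min_t=min_t, max_t=max_t, min_dn=0, max_dn=255)

    from scipy import ndimage as ndi

    mapped = true_transform.apply(
        np.column_stack([c.ravel() for c in np.meshgrid(np.arange(tw), np.arange(th))])
    )
    temp_on_thermal = ndi.map_coordinates(
        true_temp, [mapped[:, 1], mapped[:, 0]], order=1, mode="nearest"
    ).reshape(th, tw)
    dn_thermal = np.clip(np.round(scale.to_dn(temp_on_thermal)), 0, 255).astype(np.uint8)

    # legend: colour bar + dot-matrix labels in the right margin
    frame = np.zeros((th, tw + LEGEND_WIDTH_PX), dtype=np.uint8)
    frame[:, :tw] = dn_thermal
    bar_x0 = tw + 4
    frame[12:th - 12, bar_x0:bar_x0 + 6] = np.linspace(
        255, 0, th - 24
    ).astype(np.uint8)[:, None]
    top_label = render_text(f"{max_t:.1f}", scale=1)
    bot_label = render_text(f"{min_t:.1f}", scale=1)
    top_box = (tw + 2, 2, tw + LEGEND_WIDTH_PX - 2, 2 + top_label.shape[0] + 2)
    bot_box = (tw + 2, th - 11, tw + LEGEND_WIDTH_PX - 2, th - 2)

    def blit(label, box):
        x0, y0 = box[0] + 1, box[1] + 1
        lh, lw = label.shape
        frame[y0:y0 + lh, x0:x0 + lw] = np.where(label, 255, 0)

    blit(top_label, top_box)
    blit(bot_label, bot_box)
    thermal = BandImage(frame, "thermal", "dn8")

    cid = capture_id if capture_id is not None else f"synthetic-{seed}"
    capture = CaptureSet(
        rgb=rgb,
        green=spectral["green"],
        red=spectral["red"],
        red_edge=spectral["red_edge"],
        nir=spectral["nir"],
        thermal=thermal,
        capture_id=cid,
    )
    truth = SceneTruth(
        true_mask=Mask(canopy),
        true_reflectance=true_refl,
        true_temperature=BandImage(true_temp, "thermal", "celsius"),
        true_transform=true_transform,
        illumination_gradient=amp * gradient,
        scale=scale,
        ocr_region=OcrRegion(top_box=top_box, bottom_box=bot_box),
        image_area=(0, 0, tw, th),
        seed=seed,
    )
    return capture, truth
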