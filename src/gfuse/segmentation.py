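"""Canopy segmentation, masking, and eight-band stack assembly.

The RGB frame has the best spatial resolution, so the canopy/background
decision is made there and propagated to every other modality.  Plants sit
in front of a white backdrop, which makes the *excess-green* chromaticity
(2G - R - B) an almost ideal separator: the white backdrop and its shadows
are achromatic (ExG ~ 0) while leaves are strongly green.  A local adaptive
threshold on ExG (window mean plus a small offset) then tolerates residual
illumination non-uniformity; morphological opening and a minimum component
area remove speckle.

Everything outside the mask is set to NaN — the stack's nodata convention —
and the eight co-registered bands are stacked in the order
R, G, B, green, red-edge, NIR, red, thermal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.filters import threshold_local
from skimage.metrics import structural_similarity
from skimage.morphology import footprint_rectangle, opening, remove_small_objects

from .calibration import CameraModel, undistort
from .illumination import IlluminationRefs, corner_reference, gradient_correct, illumination_correct
from .raster import BandImage, CaptureSet, ContractError, STACK_BAND_ORDER
from .registration import Transform2D, warp
from .thermal import ThermalScale, rescale

__all__ = [
    "Mask",
    "CanopyStack",
    "plant_mask",
    "apply_mask",
    "build_stack",
    "seg_metrics",
    "StageError",
]

log = logging.getLogger(__name__)


class StageError(ContractError):
    """A pipeline stage failed for one capture; carries stage + capture id."""

    def __init__(self, stage: str, capture_id: str, cause: Exception):
        self.stage = stage
        self.capture_id = capture_id
        super().__init__(f"capture {capture_id!r}, stage {stage!r}: {cause}")


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class Mask:
    """Boolean canopy mask on the reference (RGB) grid."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=bool)
        if self.pixels.ndim != 2:
            raise ContractError("mask must be 2-D")

    @property
    def coverage(self) -> float:
        return float(self.pixels.mean())

    @property
    def grid(self) -> tuple:
        return self.pixels.shape


@dataclass
class CanopyStack:
    """Eight co-registered bands with non-canopy pixels set to NaN.

    Band order: R, G, B (from the RGB sensor), green, red-edge, NIR, red
    (reflectance), thermal (Celsius).
    """

    bands: list
    mask: Mask

    def __post_init__(self) -> None:
        if len(self.bands) != 8:
            raise ContractError(f"canopy stack needs exactly 8 bands, got {len(self.bands)}")
        grid = self.bands[0].grid
        for b in self.bands:
            if b.grid != grid:
                raise ContractError("stack bands must share one grid")
        if self.mask.grid != grid:
            raise ContractError("mask grid must match the stack grid")

    def band(self, name: str) -> BandImage:
        for b in self.bands:
            if b.band == name:
                return b
        raise KeyError(name)

    @property
    def band_names(self) -> tuple:
        return tuple(b.band for b in self.bands)


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------


def excess_green(rgb: BandImage) -> np.ndarray:
    """Normalised excess-green chromaticity in [0, 1]: (2G - R - B)/2, scaled."""
    px = np.asarray(rgb.pixels, dtype=float)
    if px.ndim != 3:
        raise ContractError("excess_green expects a 3-channel RGB image")
    scale = 255.0 if rgb.units == "dn8" else 65535.0 if rgb.units == "dn16" else 1.0
    r, g, b = px[:, :, 0] / scale, px[:, :, 1] / scale, px[:, :, 2] / scale
    exg = 2.0 * g - r - b  # in [-2, 2]
    return (exg + 2.0) / 4.0


def plant_mask(
    rgb: BandImage,
    window_px: int = 75,
    offset: float = 0.02,
    min_area: int = 64,
    scalar: str = "excess_green",
) -> Mask:
    """Adaptive-threshold canopy mask from the RGB frame.

    The greenness scalar is contrast-stretched to the scene's own chromatic
    range (1st-99th percentile), so ``offset`` is a fraction of the actual
    plant/backdrop contrast rather than of the theoretical ExG range.  A
    pixel is then foreground when its greenness exceeds its local window mean
    by ``offset``; a 3x3 opening and a minimum component area clean up
    speckle.  A constant or fully saturated frame yields an empty mask with
    a warning rather than an error, so batch runs keep going.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ContractError("window_px must be an odd integer >= 3")
    if scalar == "excess_green":
        img = excess_green(rgb)
    elif scalar == "greyscale":
        px = np.asarray(rgb.pixels, dtype=float)
        img = px.mean(axis=2) if px.ndim == 3 else px
        scale = 255.0 if rgb.units == "dn8" else 65535.0 if rgb.units == "dn16" else 1.0
        img = img / scale
    else:
        raise ContractError(f"unknown scalar channel {scalar!r}")

    if np.nanstd(img) < 1e-9:
        log.warning("constant/saturated RGB frame; returning an empty mask")
        return Mask(np.zeros(img.shape, dtype=bool))

    img = np.nan_to_num(img, nan=0.0)
    lo, hi = np.percentile(img, [1.0, 99.0])
    if hi - lo > 1e-9:
        img = np.clip((img - lo) / (hi - lo), 0.0, 1.0)
    # threshold_local returns window_mean - offset; we want mean + offset
    thresh = threshold_local(img, block_size=window_px, method="mean", offset=-offset)
    fg = img > thresh
    fg = opening(fg, footprint_rectangle((3, 3)))
    if min_area > 1:
        # drop components strictly smaller than min_area pixels
        fg = remove_small_objects(fg, max_size=min_area - 1)
    if not fg.any():
        log.warning("adaptive threshold found no canopy pixels")
    return Mask(fg)


def apply_mask(image: BandImage, mask: Mask) -> BandImage:
    """Set non-canopy pixels to nodata; canopy values pass through bit-exactly."""
    if image.grid != mask.grid:
        raise ContractError(
            f"grid mismatch: image {image.grid} vs mask {mask.grid}"
        )
    px = np.asarray(image.pixels, dtype=float).copy()
    if px.ndim == 3:
        px[~mask.pixels, :] = np.nan
    else:
        px[~mask.pixels] = np.nan
    return BandImage(px, image.band, image.units)


# ---------------------------------------------------------------------------
# Stack assembly
# ---------------------------------------------------------------------------


def _correct_band(img: BandImage, refs: IlluminationRefs) -> BandImage:
    g_ref = corner_reference(img, refs.corner_roi_px)
    g_cor = gradient_correct(img, g_ref)
    return illumination_correct(g_cor, refs)


def build_stack(
    capture: CaptureSet,
    transform: Transform2D,
    scale: ThermalScale,
    refs: IlluminationRefs,
    models: Optional[dict] = None,
    window_px: int = 75,
    offset: float = 0.02,
    min_area: int = 64,
    image_area: Optional[tuple] = None,
) -> CanopyStack:
    """Run one capture through the full per-capture pipeline.

    Stages, in order: undistort the spectral bands (when camera models are
    supplied), rescale the thermal frame to Celsius and warp it onto the
    common grid with ``transform`` (thermal -> reference coordinates),
    flat-field every spectral band and RGB channel to reflectance, segment
    the canopy on the RGB frame, then NaN-mask all eight bands.  Any stage
    failure is re-raised as :class:`StageError` naming the capture and stage.
    An empty mask produces an all-nodata stack with a warning, not an error.
    """
    models = models or {}
    cid = capture.capture_id

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise StageError(name, cid, exc) from exc

    # 1. undistort spectral bands
    spectral = {}
    for name, img in capture.spectral_bands().items():
        if name in models:
            img = stage(f"undistort:{name}", undistort, img, models[name])
        spectral[name] = img
    rgb = capture.rgb
    if "rgb" in models:
        rgb = stage("undistort:rgb", undistort, rgb, models["rgb"])

    # 2. thermal: DN -> Celsius, then into the common frame
    h, w = rgb.grid
    thermal_in = capture.thermal
    if image_area is not None:
        # blank the legend/scale-bar pixels so they never enter the stack
        x0, y0, x1, y1 = image_area
        px = np.asarray(thermal_in.pixels, dtype=float).copy()
        keep = np.zeros(px.shape, dtype=bool)
        keep[y0:y1, x0:x1] = True
        px[~keep] = np.nan
        thermal_in = BandImage(px, "thermal", "dn8")
    celsius = stage("thermal-rescale", rescale, thermal_in, scale)
    thermal = stage("thermal-warp", warp, celsius, transform, (w, h))

    # 3. illumination correction to reflectance
    for name, img in spectral.items():
        spectral[name] = stage(f"illumination:{name}", _correct_band, img.as_float(), refs)
    rgb_refl_channels = []
    rgb_px = np.asarray(rgb.pixels, dtype=float)
    for c, cname in enumerate(("red_rgb", "green_rgb", "blue")):
        chan = BandImage(rgb_px[:, :, c], cname, "unitless")
        rgb_refl_channels.append(stage(f"illumination:{cname}", _correct_band, chan, refs))

    # 4. segmentation on the (corrected) RGB
    rgb_for_mask = BandImage(
        np.dstack([rgb_refl_channels[0].pixels,
                   rgb_refl_channels[1].pixels,
                   rgb_refl_channels[2].pixels]),
        "rgb", "reflectance",
    )
    mask = stage("segmentation", plant_mask, rgb_for_mask, window_px, offset, min_area)
    if not mask.pixels.any():
        log.warning("capture %r: empty canopy mask; stack will be all nodata", cid)
    # pixels the thermal frame cannot see are undefined in every band
    final_mask = Mask(mask.pixels & thermal.defined())

    by_name = {
        "red_rgb": rgb_refl_channels[0],
        "green_rgb": rgb_refl_channels[1],
        "blue": rgb_refl_channels[2],
        "green": spectral["green"],
        "red_edge": spectral["red_edge"],
        "nir": spectral["nir"],
        "red": spectral["red"],
        "thermal": thermal,
    }
    bands = [stage(f"mask:{name}", apply_mask, by_name[name], final_mask)
             for name in STACK_BAND_ORDER]
    return CanopyStack(bands, final_mask)


# ---------------------------------------------------------------------------
# Segmentation quality metrics
# ---------------------------------------------------------------------------


def seg_metrics(original: BandImage, segmented: BandImage):
    """RMSE and SSIM map between an original and its segmented version.

    Both images are compared on a [0, 1] scale; nodata in ``segmented`` is
    treated as 0 (background removed).  The SSIM map uses an 11x11 Gaussian
    window with the standard stabilising constants.
    """
    if original.grid != segmented.grid:
        raise ContractError("grid mismatch between original and segmented")

    def to_unit(img):
        px = np.asarray(img.pixels, dtype=float)
        if px.ndim == 3:
            px = px.mean(axis=2)
        if img.units == "dn8":
            px = px / 255.0
        elif img.units == "dn16":
            px = px / 65535.0
        return px

    a = np.nan_to_num(to_unit(original), nan=0.0)
    b = np.nan_to_num(to_unit(segmented), nan=0.0)
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    _, ssim_map = structural_similarity(
        a, b, data_range=1.0, gaussian_weights=True, win_size=11,
        sigma=1.5, use_sample_covariance=False, full=True,
    )
    return rmse, BandImage(ssim_map, original.band if original.band != "rgb" else "green_rgb",
                           "unitless")
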