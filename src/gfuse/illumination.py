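"""Gradient removal and illumination normalisation to reflectance.

Glasshouse imaging is done under natural light, so two effects must be
undone before band values can be treated as reflectance: a *directional
gradient* (one side of the frame brighter than the other within a single
exposure) and *temporal drift* of the overall illumination level between
captures.  The backdrop behind every plant is a flat panel of known 80%
reflectance, so the image corners — which always see bare backdrop — act as
an in-scene white reference.

Per band:

1.  ``Gref``: the mean of a small ROI in each corner, bilinearly
    interpolated across the grid (a planar model of the gradient).
2.  ``Gdif = Gref - min(Gref)``; ``Gcor = Iorg - Gdif`` flattens the
    gradient without shifting the darkest corner.
3.  ``Icor = (Gcor - Idark) / (Iwhite - Idark) * ref`` rescales to
    reflectance, where ``Idark`` is a lens-capped dark capture, ``Iwhite``
    is the corner-interpolated white reference built from ``Gcor`` itself,
    and ``ref`` is the backdrop reflectance factor (0.80).

The result is clamped to [0, 1]; backdrop pixels land at ``ref`` by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .raster import BandImage, ContractError

__all__ = [
    "IlluminationRefs",
    "corner_reference",
    "gradient_correct",
    "illumination_correct",
]

log = logging.getLogger(__name__)

#: warn when a corner ROI looks like it contains canopy rather than backdrop
CORNER_VARIANCE_WARN = 0.05  # coefficient of variation within a corner ROI


@dataclass
class IlluminationRefs:
    """Session references for illumination correction."""

    dark: Optional[BandImage] = None
    corner_roi_px: int = 4
    ref_factor: float = 0.80

    def __post_init__(self) -> None:
        if self.corner_roi_px < 1:
            raise ContractError("corner ROI must be at least 1 px")
        if not (0.0 < self.ref_factor <= 1.0):
            raise ContractError("ref_factor must lie in (0, 1]")

    def dark_pixels(self, grid) -> np.ndarray:
        if self.dark is None:
            return np.zeros(grid)
        if self.dark.grid != grid:
            raise ContractError(
                f"dark reference grid {self.dark.grid} does not match {grid}"
            )
        return np.asarray(self.dark.pixels, dtype=float)


def _corner_means(img: np.ndarray, roi: int) -> np.ndarray:
    """Means of the four corner ROIs over defined pixels: [[TL, TR], [BL, BR]]."""
    corners = np.empty((2, 2))
    slices = {
        (0, 0): (slice(0, roi), slice(0, roi)),
        (0, 1): (slice(0, roi), slice(-roi, None)),
        (1, 0): (slice(-roi, None), slice(0, roi)),
        (1, 1): (slice(-roi, None), slice(-roi, None)),
    }
    for (i, j), sl in slices.items():
        patch = img[sl]
        vals = patch[np.isfinite(patch)]
        if vals.size == 0:
            raise ContractError("corner ROI contains no defined pixels")
        mean = vals.mean()
        if vals.size > 1 and mean != 0:
            cv = vals.std() / abs(mean)
            if cv > CORNER_VARIANCE_WARN:
                log.warning(
                    "corner ROI (%d,%d) variance is high (cv=%.3f); "
                    "canopy may intrude into the white-reference corners", i, j, cv
                )
        corners[i, j] = mean
    return corners


def corner_reference(image: BandImage, roi_px: int = 4) -> BandImage:
    """Bilinear gradient reference interpolated from the four corner ROIs.

    The value at each corner is the mean of its ``roi_px`` x ``roi_px``
    corner patch (NaN pixels excluded); interior values interpolate
    bilinearly, which is the minimal model for a planar gradient.
    """
    h, w = image.grid
    if h < 2 * roi_px or w < 2 * roi_px:
        raise ContractError(
            f"image {w}x{h} too small for {roi_px}-px corner ROIs"
        )
    img = np.asarray(image.pixels, dtype=float)
    if img.ndim == 3:
        raise ContractError("corner_reference expects a single-band image")
    c = _corner_means(img, roi_px)
    # anchor the surface at the ROI centres and extrapolate to the frame
    # edges, so a planar gradient is reproduced exactly
    off = (roi_px - 1) / 2.0
    u = ((np.arange(w) - off) / max(w - 1 - 2 * off, 1))[None, :]
    v = ((np.arange(h) - off) / max(h - 1 - 2 * off, 1))[:, None]
    g = ((1 - v) * (1 - u) * c[0, 0] + (1 - v) * u * c[0, 1]
         + v * (1 - u) * c[1, 0] + v * u * c[1, 1])
    return BandImage(g, image.band, image.units)


def gradient_correct(image: BandImage, g_ref: BandImage) -> BandImage:
    """Subtract the directional gradient: ``Iorg - (Gref - min(Gref))``.

    A uniform reference leaves the image untouched; at the reference's argmin
    the image is untouched by construction.
    """
    if image.grid != g_ref.grid:
        raise ContractError(
            f"grid mismatch: image {image.grid} vs reference {g_ref.grid}"
        )
    ref = np.asarray(g_ref.pixels, dtype=float)
    g_dif = ref - np.nanmin(ref)
    out = np.asarray(image.pixels, dtype=float) - g_dif
    return BandImage(out, image.band, "unitless")


def illumination_correct(g_cor: BandImage, refs: IlluminationRefs) -> BandImage:
    """Flat-field a gradient-corrected band to reflectance in [0, 1].

    The white reference is rebuilt from ``g_cor``'s own corners (bare
    backdrop), so backdrop pixels map to ``refs.ref_factor`` exactly.  Pixels
    where white and dark references coincide are undefined (guarded divide)
    and become nodata with a warning.
    """
    dark = refs.dark_pixels(g_cor.grid)
    white = corner_reference(g_cor, refs.corner_roi_px).pixels
    denom = white - dark
    bad = ~(np.abs(denom) > 1e-12)
    if bad.any():
        log.warning("white and dark references coincide at %d px; set to nodata",
                    int(bad.sum()))
    denom = np.where(bad, np.nan, denom)
    icor = (np.asarray(g_cor.pixels, dtype=float) - dark) / denom * refs.ref_factor
    icor = np.clip(icor, 0.0, 1.0)
    return BandImage(icor, g_cor.band, "reflectance")
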