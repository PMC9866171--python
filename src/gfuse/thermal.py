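"""Thermal-frame radiometric rescaling via scale-bar digit reading.

The thermal camera's export is an 8-bit screen render: pixel values are
digital numbers (DN) in 0..255, and the only temperature information is the
min/max of the colour scale printed as text next to the image.  The pipeline
therefore (1) reads those two labels with a small template-matching digit
reader, (2) scans the image area (excluding the legend) for the DN extremes,
and (3) maps DN to temperature linearly:

    T = minT + (maxT - minT) * (DN - minDN) / (maxDN - minDN)

so that ``DN = minDN`` maps to ``minT`` and ``DN = maxDN`` to ``maxT``.

The digit reader matches connected glyph components against a bundled 7x5
dot-matrix atlas (digits, minus sign, decimal point).  The synthetic fixture
generator renders its scale labels from the same atlas, so the OCR loop is
closed without an external engine; a different backend can be plugged in via
the ``reader`` argument of :func:`read_scale`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import ndimage

from .raster import BandImage, ContractError, OcrError

__all__ = [
    "ThermalScale",
    "OcrRegion",
    "read_scale",
    "rescale",
    "extract_dn_range",
    "render_text",
    "read_text",
    "DIGIT_ATLAS",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class ThermalScale:
    """Linear DN -> temperature map defined by the frame's scale bar."""

    min_t: float
    max_t: float
    min_dn: int = 0
    max_dn: int = 255

    def __post_init__(self) -> None:
        if not (self.max_t > self.min_t):
            raise ContractError("max_t must exceed min_t")
        if not (self.max_dn > self.min_dn):
            raise ContractError("max_dn must exceed min_dn")
        if not (0 <= self.min_dn <= 255 and 0 <= self.max_dn <= 255):
            raise ContractError("DN bounds must lie in [0, 255]")

    @property
    def degrees_per_dn(self) -> float:
        return (self.max_t - self.min_t) / (self.max_dn - self.min_dn)

    def to_temperature(self, dn: np.ndarray) -> np.ndarray:
        return self.min_t + self.degrees_per_dn * (np.asarray(dn, float) - self.min_dn)

    def to_dn(self, t: np.ndarray) -> np.ndarray:
        """Inverse map (used by the synthetic renderer), unquantised."""
        return self.min_dn + (np.asarray(t, float) - self.min_t) / self.degrees_per_dn


@dataclass
class OcrRegion:
    """Pixel boxes (x0, y0, x1, y1), exclusive end, locating the two labels."""

    top_box: Tuple[int, int, int, int]
    bottom_box: Tuple[int, int, int, int]

    def __post_init__(self) -> None:
        for box in (self.top_box, self.bottom_box):
            x0, y0, x1, y1 = box
            if not (x1 > x0 and y1 > y0):
                raise ContractError(f"degenerate OCR box {box}")
        ax0, ay0, ax1, ay1 = self.top_box
        bx0, by0, bx1, by1 = self.bottom_box
        if ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1:
            raise ContractError("OCR boxes overlap")


# ---------------------------------------------------------------------------
# Bundled dot-matrix digit atlas (7 rows x 5 cols per glyph)
# ---------------------------------------------------------------------------


def _glyph(rows) -> np.ndarray:
    return np.array([[c == "#" for c in row] for row in rows], dtype=bool)


DIGIT_ATLAS = {
    "0": _glyph([".###.", "#...#", "#..##", "#.#.#", "##..#", "#...#", ".###."]),
    "1": _glyph(["..#..", ".##..", "..#..", "..#..", "..#..", "..#..", ".###."]),
    "2": _glyph([".###.", "#...#", "....#", "...#.", "..#..", ".#...", "#####"]),
    "3": _glyph([".###.", "#...#", "....#", "..##.", "....#", "#...#", ".###."]),
    "4": _glyph(["...#.", "..##.", ".#.#.", "#..#.", "#####", "...#.", "...#."]),
    "5": _glyph(["#####", "#....", "####.", "....#", "....#", "#...#", ".###."]),
    "6": _glyph([".###.", "#....", "#....", "####.", "#...#", "#...#", ".###."]),
    "7": _glyph(["#####", "....#", "...#.", "..#..", ".#...", ".#...", ".#..."]),
    "8": _glyph([".###.", "#...#", "#...#", ".###.", "#...#", "#...#", ".###."]),
    "9": _glyph([".###.", "#...#", "#...#", ".####", "....#", "....#", ".###."]),
    "-": _glyph([".....", ".....", ".....", "#####", ".....", ".....", "....."]),
    ".": _glyph([".....", ".....", ".....", ".....", ".....", ".##..", ".##.."]),
}

GLYPH_H, GLYPH_W = 7, 5
_GLYPH_GAP = 1  # blank columns between glyphs when rendering


def render_text(text: str, scale: int = 2) -> np.ndarray:
    """Render a numeric string from the atlas as a boolean bitmap.

    Glyphs are replicated by an integer ``scale`` (nearest-neighbour), so a
    rendered label downsamples back onto the atlas exactly — the property the
    default reader relies on.
    """
    if scale < 1:
        raise ContractError("scale must be a positive integer")
    cols = []
    gap = np.zeros((GLYPH_H, _GLYPH_GAP), dtype=bool)
    for i, ch in enumerate(text):
        if ch not in DIGIT_ATLAS:
            raise ContractError(f"cannot render character {ch!r}")
        if i:
            cols.append(gap)
        cols.append(DIGIT_ATLAS[ch])
    bitmap = np.concatenate(cols, axis=1)
    return np.kron(bitmap, np.ones((scale, scale), dtype=bool))


def _bbox_crop(g: np.ndarray) -> np.ndarray:
    rows = np.any(g, axis=1)
    cols = np.any(g, axis=0)
    r0, r1 = np.argmax(rows), len(rows) - np.argmax(rows[::-1])
    c0, c1 = np.argmax(cols), len(cols) - np.argmax(cols[::-1])
    return g[r0:r1, c0:c1]


def _block_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Average-pool an array onto an (out_h, out_w) grid."""
    h, w = img.shape
    ys = (np.arange(out_h + 1) * h / out_h).round().astype(int)
    xs = (np.arange(out_w + 1) * w / out_w).round().astype(int)
    out = np.zeros((out_h, out_w))
    for i in range(out_h):
        for j in range(out_w):
            cell = img[ys[i]:max(ys[i + 1], ys[i] + 1), xs[j]:max(xs[j + 1], xs[j] + 1)]
            out[i, j] = cell.mean()
    return out


def _classify_glyph(crop: np.ndarray, line_h: int, top: int) -> str:
    """Match one glyph component against the atlas.

    Each candidate digit is compared on its own tight bounding box (so the
    narrow '1' is not stretched to the full cell width) after average-pooling
    the observed component onto that box — which makes matching exact for
    integer-scaled renders and tolerant of mild blur otherwise.
    """
    h, w = crop.shape
    # small marks: decide '.' vs '-' geometrically before template matching
    if h <= 0.45 * line_h:
        is_low = top + h / 2 > 0.6 * line_h
        return "." if is_low else "-"
    best, best_score = None, -1.0
    for ch in "0123456789":
        template = _bbox_crop(DIGIT_ATLAS[ch])
        resized = _block_resize(crop, *template.shape) > 0.5
        score = (resized == template).mean()
        if score > best_score:
            best, best_score = ch, score
    if best_score < 0.8:
        raise OcrError(f"glyph matched no digit (best score {best_score:.2f})")
    return best


def read_text(bitmap: np.ndarray) -> str:
    """Read a numeric string from a binary label bitmap.

    Glyphs are split by connected components, ordered left to right and
    matched against the atlas.  Raises :class:`OcrError` when nothing
    legible is present.
    """
    bitmap = np.asarray(bitmap).astype(bool)
    if not bitmap.any():
        raise OcrError("label region is blank")
    labels, n = ndimage.label(bitmap, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise OcrError("label region is blank")
    rows = np.any(bitmap, axis=1)
    y0, y1 = np.argmax(rows), len(rows) - np.argmax(rows[::-1])
    line_h = y1 - y0
    slices = ndimage.find_objects(labels)
    comps = sorted(
        (sl[1].start, sl) for sl in slices if sl is not None
    )
    out = []
    for _, sl in comps:
        crop = (labels[sl] > 0) & bitmap[sl]
        top = sl[0].start - y0
        out.append(_classify_glyph(crop.astype(float), line_h, top))
    text = "".join(out)
    return text


def _default_reader(region_pixels: np.ndarray) -> float:
    """Binarise a label box and parse it as a decimal number."""
    arr = np.asarray(region_pixels, dtype=float)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    rng = np.nanmax(arr) - np.nanmin(arr)
    if not np.isfinite(rng) or rng < 1e-9:
        raise OcrError("label region has no contrast")
    binary = (arr - np.nanmin(arr)) / rng > 0.5
    # labels may be dark-on-light or light-on-dark; glyphs are the minority
    if binary.mean() > 0.5:
        binary = ~binary
    # trim empty margins (interior gaps between glyphs must survive)
    rows = np.any(binary, axis=1)
    cols = np.any(binary, axis=0)
    if not rows.any():
        raise OcrError("label region is blank")
    r0, r1 = np.argmax(rows), len(rows) - np.argmax(rows[::-1])
    c0, c1 = np.argmax(cols), len(cols) - np.argmax(cols[::-1])
    binary = binary[r0:r1, c0:c1]
    text = read_text(binary)
    try:
        return float(text)
    except ValueError as exc:
        raise OcrError(f"unparseable label text {text!r}") from exc


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def read_scale(
    frame: BandImage,
    region: OcrRegion,
    reader: Optional[Callable[[np.ndarray], float]] = None,
) -> Tuple[float, float]:
    """Read (min_t, max_t) from the scale-bar labels of a thermal frame.

    The maximum temperature sits in the top box, the minimum in the bottom
    box.  Raises :class:`OcrError` for unreadable labels or an inverted
    scale; callers may fall back to configured override values.
    """
    if frame.units != "dn8":
        raise ContractError("thermal frames must be 8-bit DN renders")
    reader = reader or _default_reader
    h, w = frame.grid

    def crop(box):
        x0, y0, x1, y1 = box
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ContractError(f"OCR box {box} outside the {w}x{h} frame")
        return frame.pixels[y0:y1, x0:x1]

    max_t = reader(crop(region.top_box))
    min_t = reader(crop(region.bottom_box))
    if not (np.isfinite(min_t) and np.isfinite(max_t)) or min_t >= max_t:
        raise OcrError(f"implausible scale labels: min {min_t}, max {max_t}")
    log.info("thermal scale OCR: min %.2f C, max %.2f C", min_t, max_t)
    return float(min_t), float(max_t)


def extract_dn_range(frame: BandImage, image_area) -> Tuple[int, int]:
    """Min and max DN of the defined pixels inside the image area.

    ``image_area`` is an (x0, y0, x1, y1) box that must exclude the legend —
    otherwise the scale-bar gradient and label text corrupt the range.
    """
    x0, y0, x1, y1 = image_area
    if x1 <= x0 or y1 <= y0:
        raise ContractError(f"empty image area {image_area}")
    sub = np.asarray(frame.pixels, dtype=float)[y0:y1, x0:x1]
    vals = sub[np.isfinite(sub)]
    if vals.size == 0:
        raise ContractError("image area contains no defined pixels")
    return int(vals.min()), int(vals.max())


def rescale(frame: BandImage, scale: ThermalScale) -> BandImage:
    """Convert an 8-bit DN thermal frame to degrees Celsius.

    DNs outside ``[min_dn, max_dn]`` are clamped with a warning; nodata
    propagates.  A degenerate scale (``max_dn == min_dn``) is rejected at
    :class:`ThermalScale` construction.
    """
    if frame.units != "dn8":
        raise ContractError("rescale expects an 8-bit DN frame")
    dn = np.asarray(frame.pixels, dtype=float)
    defined = np.isfinite(dn)
    out_of_range = defined & ((dn < scale.min_dn) | (dn > scale.max_dn))
    if out_of_range.any():
        log.warning("%d DN values outside [%d, %d]; clamping",
                    int(out_of_range.sum()), scale.min_dn, scale.max_dn)
        dn = np.clip(dn, scale.min_dn, scale.max_dn)
    temp = scale.to_temperature(dn)
    temp[~defined] = np.nan
    return BandImage(temp, "thermal", "celsius")
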