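"""Core raster data model and image I/O.

A :class:`BandImage` is the pipeline's universal currency: one 2-D raster of a
single modality/band, tagged with its physical units and carrying NaN as the
nodata sentinel.  Undefined pixels compare unequal to everything and propagate
through arithmetic, which is exactly the behaviour the eight-band canopy stack
relies on (background pixels are NaN in every band).

Coordinate convention used throughout the package: row-major arrays, 0-based
indices, pixel centres at integer coordinates, ``x`` = column, ``y`` = row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from PIL import Image

__all__ = [
    "Band",
    "Units",
    "BandImage",
    "SensorSpec",
    "CaptureSet",
    "GfuseError",
    "ContractError",
    "FormatError",
    "DetectionError",
    "RegistrationError",
    "OcrError",
    "read_image",
    "write_stack",
    "read_stack",
    "natural_sort",
    "STACK_BAND_ORDER",
]

# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class GfuseError(Exception):
    """Base class for pipeline errors."""


class ContractError(GfuseError):
    """A call violated an operation's precondition."""


class FormatError(GfuseError):
    """A file decoded, but not to the layout the caller asked for."""


class DetectionError(GfuseError):
    """A pattern/feature detector found nothing usable."""


class RegistrationError(GfuseError):
    """Image alignment failed (no consensus / no overlap)."""


class OcrError(GfuseError):
    """The thermal scale-bar labels could not be parsed."""


# ---------------------------------------------------------------------------
# Band / unit vocabulary
# ---------------------------------------------------------------------------

#: Band names understood by the pipeline.  ``green_rgb``/``red_rgb``/``blue``
#: are the colour channels of the RGB sensor; ``green``/``red``/``red_edge``/
#: ``nir`` are the narrow-band multispectral channels; ``thermal`` is the
#: 8-bit screen render of the radiometric frame.
BANDS = (
    "blue",
    "green_rgb",
    "red_rgb",
    "green",
    "red",
    "red_edge",
    "nir",
    "thermal",
)

UNITS = ("dn8", "dn16", "reflectance", "celsius", "unitless")

Band = str
Units = str

#: Order of the eight bands in the output stack: RGB first, then green,
#: red-edge, NIR, red, and thermal last.
STACK_BAND_ORDER = (
    "red_rgb",
    "green_rgb",
    "blue",
    "green",
    "red_edge",
    "nir",
    "red",
    "thermal",
)

_UNIT_RANGE = {"dn8": (0.0, 255.0), "dn16": (0.0, 65535.0), "reflectance": (0.0, 1.0)}


# ---------------------------------------------------------------------------
# BandImage
# ---------------------------------------------------------------------------


@dataclass
class BandImage:
    """One 2-D raster (or an H x W x 3 RGB raster) with units and nodata.

    Parameters
    ----------
    pixels:
        2-D float/int array, or 3-D with a trailing channel axis of 3 for RGB.
    band:
        One of :data:`BANDS`, or ``"rgb"`` for a 3-channel image.
    units:
        One of :data:`UNITS`.
    """

    pixels: np.ndarray
    band: Band
    units: Units = "unitless"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ContractError(f"pixels must be 2-D or 3-D, got ndim={self.pixels.ndim}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ContractError("3-D pixel arrays must have exactly 3 channels")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ContractError("pixels must have positive height and width")
        if self.band != "rgb" and self.band not in BANDS:
            raise ContractError(f"unknown band {self.band!r}")
        if self.units not in UNITS:
            raise ContractError(f"unknown units {self.units!r}")
        rng = _UNIT_RANGE.get(self.units)
        if rng is not None and self.pixels.size:
            vals = self.pixels[self.defined()] if self.is_float else self.pixels
            if vals.size and (np.min(vals) < rng[0] or np.max(vals) > rng[1]):
                raise ContractError(
                    f"units={self.units}: defined values outside [{rng[0]}, {rng[1]}]"
                )

    # -- nodata handling ----------------------------------------------------

    @property
    def is_float(self) -> bool:
        return np.issubdtype(self.pixels.dtype, np.floating)

    def defined(self) -> np.ndarray:
        """Boolean mask of defined (non-nodata) pixels on the 2-D grid."""
        if not self.is_float:
            return np.ones(self.pixels.shape[:2], dtype=bool)
        finite = np.isfinite(self.pixels)
        return finite.all(axis=2) if self.pixels.ndim == 3 else finite

    def as_float(self) -> "BandImage":
        """Copy with float64 pixels (ints pass through unchanged in value)."""
        return BandImage(self.pixels.astype(np.float64), self.band, self.units)

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def grid(self) -> tuple:
        """(height, width) of the pixel grid, ignoring any channel axis."""
        return self.pixels.shape[:2]


@dataclass
class SensorSpec:
    """Static description of one sensor: resolution and band metadata."""

    name: str
    width_px: int
    height_px: int
    band_centres_nm: dict = field(default_factory=dict)
    band_widths_nm: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ContractError("sensor resolution must be positive")
        if set(self.band_centres_nm) != set(self.band_widths_nm):
            raise ContractError("band centre/width keys must match")


#: Default sensor metadata: a 640x480 thermal camera and a multispectral
#: camera with green/red/red-edge/NIR channels plus a high-resolution RGB.
MULTISPEC_SENSOR = SensorSpec(
    "multispectral",
    1290,
    960,
    band_centres_nm={"green": 550, "red": 660, "red_edge": 735, "nir": 790},
    band_widths_nm={"green": 40, "red": 40, "red_edge": 10, "nir": 40},
)
THERMAL_SENSOR = SensorSpec("thermal", 640, 480)
RGB_SENSOR = SensorSpec("rgb", 4608, 3695)


@dataclass
class CaptureSet:
    """All rasters of one plant capture: RGB + four spectral bands + thermal.

    The RGB and spectral rasters share one pixel grid; the thermal frame may
    differ in size until it is registered onto the common grid.
    """

    rgb: BandImage
    green: BandImage
    red: BandImage
    red_edge: BandImage
    nir: BandImage
    thermal: BandImage
    capture_id: str = ""

    def __post_init__(self) -> None:
        grid = self.rgb.grid
        for name in ("green", "red", "red_edge", "nir"):
            img = getattr(self, name)
            if img.grid != grid:
                raise ContractError(
                    f"band {name!r} grid {img.grid} differs from RGB grid {grid}"
                )

    def spectral_bands(self) -> dict:
        return {
            "green": self.green,
            "red": self.red,
            "red_edge": self.red_edge,
            "nir": self.nir,
        }


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------


def read_image(path, band: Band) -> BandImage:
    """Read an 8/16-bit PNG/JPEG/TIFF as a :class:`BandImage`.

    Pixel values are preserved bit-exactly; units are inferred from the bit
    depth (``dn8`` or ``dn16``).  Requesting ``band="rgb"`` from a 1-channel
    file (or a single band from a colour file) raises :class:`FormatError`.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(str(path))
        else:
            arr = np.asarray(Image.open(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoding failure -> I/O error naming the path
        raise OSError(f"could not read image {path}: {exc}") from exc

    if band == "rgb":
        if arr.ndim != 3 or arr.shape[2] < 3:
            raise FormatError(f"{path}: RGB requested but file has 1 channel")
        arr = arr[:, :, :3]
    else:
        if arr.ndim == 3:
            raise FormatError(f"{path}: single band {band!r} requested from colour file")

    if arr.dtype == np.uint8:
        units = "dn8"
    elif arr.dtype == np.uint16:
        units = "dn16"
    else:
        units = "unitless"
    return BandImage(arr, band, units)


def write_image(image: BandImage, path) -> None:
    """Write a BandImage to PNG/JPEG/TIFF, preserving dtype."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), image.pixels)
    else:
        Image.fromarray(image.pixels).save(path)


def write_stack(stack, path) -> None:
    """Write an eight-band canopy stack as a 32-bit float multiband TIFF.

    NaN background pixels are stored as IEEE NaN; band names go into the TIFF
    ImageDescription metadata as JSON.  Exactly eight bands are required.
    """
    bands = stack.bands if hasattr(stack, "bands") else list(stack)
    if len(bands) != 8:
        raise ContractError(f"stack must have exactly 8 bands, got {len(bands)}")
    grid = bands[0].grid
    for b in bands:
        if b.grid != grid:
            raise ContractError("all stack bands must share one grid")
    data = np.stack([b.pixels.astype(np.float32) for b in bands], axis=0)
    names = [b.band for b in bands]
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        metadata={"axes": "CYX", "band_names": names, "band_units": [b.units for b in bands]},
    )


def read_stack(path) -> list:
    """Read back a stack written by :func:`write_stack` as a list of BandImages."""
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    names = meta.get("band_names", [f"band{i}" for i in range(data.shape[0])])
    units = meta.get("band_units", ["unitless"] * data.shape[0])
    out = []
    for i in range(data.shape[0]):
        band = names[i] if names[i] in BANDS else "thermal" if names[i] == "thermal" else names[i]
        out.append(BandImage(data[i], band if band in BANDS else "nir", units[i]))
    return out


# ---------------------------------------------------------------------------
# Natural-order sorting
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"(\d+)")


def _natural_key(path) -> tuple:
    parts = _NUM_RE.split(str(path))
    # even indices: text runs, odd: digit runs
    return tuple((1, int(p)) if p.isdigit() else (0, p) for p in parts if p != "")


def natural_sort(paths: Iterable) -> list:
    """Sort file names so numeric substrings compare as integers.

    ``img2`` sorts before ``img10``; the sort is stable, so equal keys keep
    their input order.
    """
    return sorted(paths, key=_natural_key)
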