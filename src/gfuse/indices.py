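"""Vegetation indices computed from the eight-band canopy stack.

Each index is an elementwise arithmetic combination of reflectance bands;
undefined (background) pixels stay NaN, and pixels where a denominator hits
zero become NaN too.  Besides the built-in indices, arbitrary user
expressions over the band names (``NIR``, ``RED``, ``RED_EDGE``, ``GREEN``,
``BLUE``, ``R``, ``G``, ``B``, ``THERMAL``) are supported through a small,
safe arithmetic parser (no general Python evaluation).

Built-in indices
----------------
========  ============================================  =====================
name      formula                                       interpretation
========  ============================================  =====================
NDVI      (NIR - RED) / (NIR + RED)                     green biomass, [-1,1]
NDRE      (NIR - RE) / (NIR + RE)                       late-stage chlorophyll
CIre      NIR / RE - 1                                  chlorophyll (red edge)
TVI       0.5 (120 (NIR - G) - 200 (RED - G))           chlorophyll absorption
RDVI      (NIR - RED) / sqrt(NIR + RED)                 soil-robust NDVI
CVI       NIR * RED / G^2                               canopy chlorophyll
CIg       NIR / G - 1                                   chlorophyll (green)
========  ============================================  =====================
"""

from __future__ import annotations

import ast
import logging
from dataclasses import dataclass
from typing import Dict

import numpy as np

from .raster import BandImage, ContractError
from .segmentation import CanopyStack

__all__ = ["VIResult", "compute_vi", "custom_vi", "BUILTIN_VIS", "ExpressionError"]

log = logging.getLogger(__name__)


class ExpressionError(ContractError):
    """A custom index expression failed to parse or referenced unknown bands."""


BUILTIN_VIS: Dict[str, str] = {
    "NDVI": "(NIR - RED) / (NIR + RED)",
    "NDRE": "(NIR - RED_EDGE) / (NIR + RED_EDGE)",
    "CIre": "NIR / RED_EDGE - 1",
    "TVI": "0.5 * (120 * (NIR - GREEN) - 200 * (RED - GREEN))",
    "RDVI": "(NIR - RED) / sqrt(NIR + RED)",
    "CVI": "NIR * RED / (GREEN * GREEN)",
    "CIg": "NIR / GREEN - 1",
}

#: expression name -> stack band name
_BAND_ALIASES = {
    "NIR": "nir",
    "RED": "red",
    "RED_EDGE": "red_edge",
    "REDEDGE": "red_edge",
    "GREEN": "green",
    "R": "red_rgb",
    "G": "green_rgb",
    "B": "blue",
    "BLUE": "blue",
    "THERMAL": "thermal",
}

_SPECTRAL = {"nir", "red", "red_edge", "green"}


@dataclass
class VIResult:
    """A computed index raster plus summary statistics over defined pixels."""

    name: str
    pixels: BandImage
    mean: float
    median: float
    sd: float


# ---------------------------------------------------------------------------
# Safe expression evaluation
# ---------------------------------------------------------------------------

_ALLOWED_BINOPS = {ast.Add: np.add, ast.Sub: np.subtract,
                   ast.Mult: np.multiply, ast.Div: np.divide,
                   ast.Pow: np.power}


def _eval_node(node, env):
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, env)
    if isinstance(node, ast.Constant):
        if isinstance(node.value, (int, float)):
            return float(node.value)
        raise ExpressionError(f"non-numeric constant {node.value!r}")
    if isinstance(node, ast.Name):
        key = node.id.upper()
        if key not in env:
            raise ExpressionError(
                f"unknown band {node.id!r} at column {node.col_offset}"
            )
        return env[key]
    if isinstance(node, ast.BinOp) and type(node.op) in _ALLOWED_BINOPS:
        left = _eval_node(node.left, env)
        right = _eval_node(node.right, env)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = _ALLOWED_BINOPS[type(node.op)](left, right)
        if isinstance(node.op, ast.Div):
            out = np.where(np.isinf(out), np.nan, out)
        return out
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
        val = _eval_node(node.operand, env)
        return -val if isinstance(node.op, ast.USub) else val
    if isinstance(node, ast.Call):
        if isinstance(node.func, ast.Name) and node.func.id == "sqrt" and len(node.args) == 1:
            with np.errstate(invalid="ignore"):
                return np.sqrt(_eval_node(node.args[0], env))
        raise ExpressionError("only sqrt(...) calls are allowed")
    raise ExpressionError(
        f"unsupported syntax at column {getattr(node, 'col_offset', '?')}"
    )


def _band_env(stack: CanopyStack, expression: str) -> dict:
    names = {b.band for b in stack.bands}
    env = {}
    used_thermal = False
    for alias, band in _BAND_ALIASES.items():
        if band in names:
            img = stack.band(band)
            env[alias] = np.asarray(img.pixels, dtype=float)
            if band == "thermal":
                pass
    if "THERMAL" in expression.upper():
        used_thermal = True
    if used_thermal:
        log.warning("index expression mixes thermal (Celsius) with reflectance "
                    "bands; unit consistency is the caller's responsibility")
    return env


def _evaluate(stack: CanopyStack, name: str, expression: str) -> VIResult:
    for b in stack.bands:
        if b.band in _SPECTRAL and b.units != "reflectance" \
                and b.band.upper().replace("-", "_") in expression.upper():
            raise ContractError(
                f"band {b.band!r} is in {b.units}, not reflectance"
            )
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(
            f"cannot parse {expression!r} at offset {exc.offset}"
        ) from exc
    env = _band_env(stack, expression)
    out = _eval_node(tree, env)
    out = np.asarray(out, dtype=float)
    if out.ndim == 0:
        out = np.full(stack.bands[0].grid, float(out))
    result = BandImage(out, "nir", "unitless")
    # force the nodata union of all inputs (constants carry no mask)
    undefined = ~stack.mask.pixels
    px = result.pixels.copy()
    px[undefined] = np.nan
    result = BandImage(px, "nir", "unitless")
    vals = px[np.isfinite(px)]
    if vals.size:
        mean, median, sd = float(vals.mean()), float(np.median(vals)), float(vals.std())
    else:
        mean = median = sd = float("nan")
    return VIResult(name, result, mean, median, sd)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def compute_vi(stack: CanopyStack, name: str) -> VIResult:
    """Compute a built-in vegetation index (see :data:`BUILTIN_VIS`)."""
    if name not in BUILTIN_VIS:
        raise ContractError(
            f"unknown index {name!r}; built-ins: {', '.join(BUILTIN_VIS)} "
            "(use custom_vi for arbitrary expressions)"
        )
    return _evaluate(stack, name, BUILTIN_VIS[name])


def custom_vi(stack: CanopyStack, expression: str, name: str = "custom") -> VIResult:
    """Evaluate a user-supplied arithmetic expression over the band names.

    Supported syntax: ``+ - * / **``, unary minus, ``sqrt(...)``, numeric
    constants, and the band names NIR, RED, RED_EDGE, GREEN, R, G, B, BLUE,
    THERMAL (case-insensitive).  Division by zero and any undefined input
    pixel yield nodata.
    """
    return _evaluate(stack, name, expression)
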