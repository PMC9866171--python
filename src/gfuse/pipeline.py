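"""Batch orchestration: discover capture sets, run the pipeline, report.

This module is the programmatic core behind the command line: a
:class:`PipelineConfig` (usually loaded from YAML) names the input directory,
the session sidecar files (per-band calibration, coarse transform, dark
reference), and the per-stage settings; :func:`run_batch` then processes
every complete capture set it can discover, writing one eight-band stack,
the requested vegetation-index rasters, and one metrics row per capture.

Per-capture failures are logged and skipped — a glasshouse run should never
abort because one frame is corrupt — but they are reflected in the summary
and the process exit status.
"""

from __future__ import annotations

import csv
import logging
import re
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .calibration import CalibrationResult, CameraModel
from .illumination import IlluminationRefs
from .indices import compute_vi, custom_vi
from .raster import BandImage, CaptureSet, ContractError, natural_sort, read_image, write_stack
from .registration import Transform2D, fine_register, mattes_mmi, warp
from .segmentation import apply_mask, build_stack, seg_metrics
from .thermal import OcrRegion, ThermalScale, extract_dn_range, read_scale

__all__ = [
    "PipelineConfig",
    "run_batch",
    "save_camera_model",
    "load_camera_model",
    "save_transform",
    "load_transform",
]

log = logging.getLogger(__name__)

#: filename suffix -> band, for capture discovery
BAND_SUFFIXES = {
    "rgb": "rgb",
    "green": "green",
    "red": "red",
    "rededge": "red_edge",
    "red_edge": "red_edge",
    "nir": "nir",
    "thermal": "thermal",
}


# ---------------------------------------------------------------------------
# Sidecar I/O
# ---------------------------------------------------------------------------


def save_camera_model(result: CalibrationResult, path) -> None:
    m = result.model
    doc = {
        "band": m.band,
        "intrinsics": {"fx": float(m.fx), "fy": float(m.fy), "cx": float(m.cx),
                       "cy": float(m.cy), "s": float(m.s)},
        "distortion": {"k1": float(m.k1), "k2": float(m.k2), "k3": float(m.k3)},
        "per_image_reproj_err_px": [float(e) for e in result.per_image_reproj_err_px],
        "mean_reproj_err_px": float(result.mean_reproj_err_px),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_camera_model(path) -> CameraModel:
    doc = yaml.safe_load(Path(path).read_text())
    i, d = doc["intrinsics"], doc["distortion"]
    return CameraModel(fx=i["fx"], fy=i["fy"], cx=i["cx"], cy=i["cy"],
                       s=i.get("s", 0.0), k1=d["k1"], k2=d["k2"], k3=d["k3"],
                       band=doc.get("band", "nir"))


def save_transform(t: Transform2D, path, session: str = "") -> None:
    doc = {"kind": t.kind, "matrix": np.asarray(t.matrix).tolist(), "session": session}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_transform(path) -> Transform2D:
    doc = yaml.safe_load(Path(path).read_text())
    return Transform2D(np.array(doc["matrix"], dtype=float), doc.get("kind", "affine"))


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Everything :func:`run_batch` needs, normally loaded from YAML."""

    input_dir: str
    output_dir: str
    transform_path: Optional[str] = None
    calibration_paths: dict = dc_field(default_factory=dict)  # band -> sidecar
    dark_path: Optional[str] = None

    # thermal
    ocr_top_box: Optional[tuple] = None
    ocr_bottom_box: Optional[tuple] = None
    thermal_image_area: Optional[tuple] = None
    scale_override_min: Optional[float] = None
    scale_override_max: Optional[float] = None

    # illumination
    corner_roi_px: int = 4
    ref_factor: float = 0.80

    # segmentation
    window_px: int = 75
    seg_offset: float = 0.02
    min_area: int = 64

    # registration
    fine_registration: bool = True
    mmi_bins: int = 64

    vis: list = dc_field(default_factory=lambda: ["NDVI", "NDRE", "CIre"])
    custom_expressions: dict = dc_field(default_factory=dict)
    seed: int = 42

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        flat = {}
        paths = doc.get("paths", {})
        flat["input_dir"] = paths.get("input_dir", doc.get("input_dir", "."))
        flat["output_dir"] = paths.get("output_dir", doc.get("output_dir", "out"))
        flat["transform_path"] = paths.get("transform", doc.get("transform_path"))
        flat["calibration_paths"] = paths.get("calibration", {})
        thermal = doc.get("thermal", {})
        ocr = thermal.get("ocr", {})
        if "top_box" in ocr:
            flat["ocr_top_box"] = tuple(ocr["top_box"])
        if "bottom_box" in ocr:
            flat["ocr_bottom_box"] = tuple(ocr["bottom_box"])
        if "image_area" in thermal:
            flat["thermal_image_area"] = tuple(thermal["image_area"])
        scl = thermal.get("scale", {})
        flat["scale_override_min"] = scl.get("override_min")
        flat["scale_override_max"] = scl.get("override_max")
        illum = doc.get("illum", {})
        flat["dark_path"] = illum.get("dark_path", paths.get("dark"))
        flat["corner_roi_px"] = illum.get("corner_roi_px", 4)
        flat["ref_factor"] = illum.get("ref_factor", 0.80)
        seg = doc.get("segmentation", {})
        flat["window_px"] = seg.get("window", 75)
        flat["seg_offset"] = seg.get("offset", 0.02)
        flat["min_area"] = seg.get("min_area", 64)
        reg = doc.get("registration", {})
        flat["fine_registration"] = reg.get("fine", True)
        flat["mmi_bins"] = reg.get("bins", 64)
        flat["vis"] = doc.get("indices", {}).get("vi", ["NDVI", "NDRE", "CIre"])
        flat["custom_expressions"] = doc.get("indices", {}).get("expressions", {})
        flat["seed"] = doc.get("seed", 42)
        return cls(**flat)


# ---------------------------------------------------------------------------
# Capture discovery
# ---------------------------------------------------------------------------

_FILE_RE = re.compile(r"^(?P<id>.+?)_(?P<band>[a-z_]+)\.(png|jpg|jpeg|tif|tiff)$", re.I)


def discover_captures(input_dir) -> dict:
    """Group files of ``<capture_id>_<band>.<ext>`` into capture sets.

    Files load in natural order, so capture ids come out the way a human
    numbers them (plant2 before plant10).  Returns ``{capture_id: {band:
    path}}`` for the complete sets; incomplete sets are logged and dropped.
    """
    required = {"rgb", "green", "red", "red_edge", "nir", "thermal"}
    found: dict = {}
    paths = natural_sort(p for p in Path(input_dir).iterdir() if p.is_file())
    for p in paths:
        m = _FILE_RE.match(p.name)
        if not m:
            continue
        band = BAND_SUFFIXES.get(m.group("band").lower())
        if band is None:
            continue
        found.setdefault(m.group("id"), {})[band] = p
    complete = {}
    for cid, bands in found.items():
        missing = required - set(bands)
        if missing:
            log.warning("capture %r missing bands %s; skipped", cid, sorted(missing))
        else:
            complete[cid] = bands
    return complete


def load_capture(cid: str, bands: dict) -> CaptureSet:
    return CaptureSet(
        rgb=read_image(bands["rgb"], "rgb"),
        green=read_image(bands["green"], "green"),
        red=read_image(bands["red"], "red"),
        red_edge=read_image(bands["red_edge"], "red_edge"),
        nir=read_image(bands["nir"], "nir"),
        thermal=read_image(bands["thermal"], "thermal"),
        capture_id=cid,
    )


# ---------------------------------------------------------------------------
# Batch run
# ---------------------------------------------------------------------------


def _thermal_scale(capture: CaptureSet, cfg: PipelineConfig) -> ThermalScale:
    if cfg.scale_override_min is not None and cfg.scale_override_max is not None:
        min_t, max_t = cfg.scale_override_min, cfg.scale_override_max
    else:
        if cfg.ocr_top_box is None or cfg.ocr_bottom_box is None:
            raise ContractError(
                "no OCR boxes configured and no scale override given"
            )
        region = OcrRegion(tuple(cfg.ocr_top_box), tuple(cfg.ocr_bottom_box))
        min_t, max_t = read_scale(capture.thermal, region)
    area = cfg.thermal_image_area or (0, 0, capture.thermal.grid[1], capture.thermal.grid[0])
    min_dn, max_dn = extract_dn_range(capture.thermal, area)
    return ThermalScale(min_t=min_t, max_t=max_t, min_dn=min_dn, max_dn=max_dn)


def process_capture(capture: CaptureSet, cfg: PipelineConfig,
                    transform: Transform2D, models: dict,
                    refs: IlluminationRefs, out_dir: Path) -> dict:
    """Run one capture end to end; returns its metrics row."""
    scale = _thermal_scale(capture, cfg)

    t = transform
    if cfg.fine_registration:
        h, w = capture.rgb.grid
        grey = BandImage(np.asarray(capture.rgb.pixels, float).mean(axis=2),
                         "green_rgb", "unitless")
        t = fine_register(grey, _blank_legend(capture.thermal, cfg), t,
                          bins=cfg.mmi_bins, seed=cfg.seed)

    stack = build_stack(
        capture, t, scale, refs, models=models,
        window_px=cfg.window_px, offset=cfg.seg_offset, min_area=cfg.min_area,
        image_area=cfg.thermal_image_area,
    )
    stack_path = out_dir / f"{capture.capture_id}_stack.tif"
    write_stack(stack, stack_path)

    # metrics
    h, w = capture.rgb.grid
    grey = BandImage(np.asarray(capture.rgb.pixels, float).mean(axis=2),
                     "green_rgb", "unitless")
    moved = warp(_blank_legend(capture.thermal, cfg), t, (w, h))
    mmi = mattes_mmi(grey, moved, bins=cfg.mmi_bins)
    rgb_seg = apply_mask(BandImage(np.asarray(capture.rgb.pixels, float), "rgb",
                                   capture.rgb.units), stack.mask)
    rmse, ssim_map = seg_metrics(capture.rgb, rgb_seg)
    row = {
        "capture_id": capture.capture_id,
        "mmi_bits": round(mmi, 4),
        "seg_rmse": round(rmse, 4),
        "mean_ssim": round(float(np.nanmean(ssim_map.pixels)), 4),
        "mask_coverage_pct": round(100.0 * stack.mask.coverage, 2),
    }
    import tifffile

    for name in cfg.vis:
        vi = compute_vi(stack, name)
        tifffile.imwrite(str(out_dir / f"{capture.capture_id}_{name}.tif"),
                         vi.pixels.pixels.astype(np.float32))
        row[f"{name}_mean"] = round(vi.mean, 4)
    for name, expr in cfg.custom_expressions.items():
        vi = custom_vi(stack, expr, name=name)
        tifffile.imwrite(str(out_dir / f"{capture.capture_id}_{name}.tif"),
                         vi.pixels.pixels.astype(np.float32))
        row[f"{name}_mean"] = round(vi.mean, 4)
    return row


def _blank_legend(thermal: BandImage, cfg: PipelineConfig) -> BandImage:
    if cfg.thermal_image_area is None:
        return thermal
    x0, y0, x1, y1 = cfg.thermal_image_area
    px = np.asarray(thermal.pixels, dtype=float).copy()
    keep = np.zeros(px.shape, dtype=bool)
    keep[y0:y1, x0:x1] = True
    px[~keep] = np.nan
    return BandImage(px, thermal.band, thermal.units)


def run_batch(cfg: PipelineConfig) -> dict:
    """Process every complete capture set under ``cfg.input_dir``.

    Returns a summary dict with per-capture metric rows and the list of
    failures; also writes ``metrics.csv`` to the output directory.  Raises
    :class:`ContractError` when the input directory holds no capture set.
    """
    captures = discover_captures(cfg.input_dir)
    if not captures:
        raise ContractError(f"no complete capture sets found in {cfg.input_dir}")
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    transform = (load_transform(cfg.transform_path)
                 if cfg.transform_path else Transform2D.identity())
    models = {band: load_camera_model(p) for band, p in cfg.calibration_paths.items()}
    dark = read_image(cfg.dark_path, "green").as_float() if cfg.dark_path else None
    refs = IlluminationRefs(dark=dark, corner_roi_px=cfg.corner_roi_px,
                            ref_factor=cfg.ref_factor)

    rows, failures = [], []
    for cid, bands in captures.items():
        t0 = time.perf_counter()
        try:
            capture = load_capture(cid, bands)
            row = process_capture(capture, cfg, transform, models, refs, out_dir)
            rows.append(row)
            log.info("capture %r done in %.2fs: %s", cid,
                     time.perf_counter() - t0, row)
        except Exception as exc:
            log.error("capture %r failed: %s", cid, exc)
            failures.append({"capture_id": cid, "error": str(exc)})

    if rows:
        csv_path = out_dir / "metrics.csv"
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    return {"processed": rows, "failures": failures,
            "n_ok": len(rows), "n_failed": len(failures)}
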