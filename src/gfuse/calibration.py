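"""Checkerboard camera calibration and radial-distortion removal.

The multispectral camera's narrow-band lenses show appreciable barrel
distortion, so each band is calibrated independently against a planar
checkerboard and undistorted before registration.

Camera model
------------
World board points ``P = (X, Y, 0)`` are mapped through per-view extrinsics
``(R, t)`` to camera coordinates, perspective-divided to normalised image
coordinates ``(x, y)``, radially distorted with the Brown series

    x_d = x * (1 + k1 r^2 + k2 r^4 + k3 r^6),   r^2 = x^2 + y^2

and finally scaled into pixels by the intrinsics ``fx, fy, cx, cy`` (skew is
fixed to zero by default; glasshouse sensors have none worth modelling).

Calibration follows the standard planar (homography-based) bootstrap: a DLT
homography per view, a closed-form intrinsic estimate from the homography
constraints, extrinsics factored from each homography, then a full nonlinear
reprojection-error minimisation over intrinsics, distortion, and all poses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation
from scipy import ndimage
from skimage.feature import corner_harris, corner_peaks, corner_subpix

from .raster import BandImage, ContractError, DetectionError

__all__ = [
    "CameraModel",
    "CheckerboardSpec",
    "CalibrationResult",
    "detect_corners",
    "calibrate",
    "undistort",
    "InsufficientDataError",
]

log = logging.getLogger(__name__)


class InsufficientDataError(ContractError):
    """Fewer calibration views than the method needs."""


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class CameraModel:
    """Pinhole intrinsics + radial distortion for one band."""

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    s: float = 0.0
    band: str = "nir"

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ContractError("focal lengths must be positive")

    # -- distortion in normalised coordinates -------------------------------

    def distort_normalised(self, x: np.ndarray, y: np.ndarray):
        """Apply the radial series to ideal normalised coordinates."""
        r2 = x * x + y * y
        d = 1.0 + r2 * (self.k1 + r2 * (self.k2 + r2 * self.k3))
        return x * d, y * d

    def undistort_normalised(self, xd: np.ndarray, yd: np.ndarray,
                             tol: float = 1e-8, max_iter: int = 20):
        """Invert the radial series by Newton iteration on the radius.

        Distortion is purely radial, so it preserves direction: solving
        ``r (1 + k1 r^2 + k2 r^4 + k3 r^6) = r_d`` for ``r`` recovers the
        ideal point as ``(xd, yd) * r / r_d``.
        """
        xd = np.asarray(xd, dtype=float)
        yd = np.asarray(yd, dtype=float)
        rd = np.hypot(xd, yd)
        r = rd.copy()
        for _ in range(max_iter):
            r2 = r * r
            f = r * (1.0 + r2 * (self.k1 + r2 * (self.k2 + r2 * self.k3))) - rd
            df = 1.0 + r2 * (3.0 * self.k1 + r2 * (5.0 * self.k2 + 7.0 * self.k3 * r2))
            step = f / np.where(np.abs(df) < 1e-12, 1e-12, df)
            r = r - step
            if np.all(np.abs(step) < tol):
                break
        scale = np.where(rd > 0, r / np.where(rd == 0, 1.0, rd), 1.0)
        return xd * scale, yd * scale

    # -- pixel <-> normalised ------------------------------------------------

    def to_pixels(self, x: np.ndarray, y: np.ndarray):
        return self.fx * x + self.s * y + self.cx, self.fy * y + self.cy

    def from_pixels(self, u: np.ndarray, v: np.ndarray):
        y = (np.asarray(v, float) - self.cy) / self.fy
        x = (np.asarray(u, float) - self.cx - self.s * y) / self.fx
        return x, y

    def project(self, pts_world: np.ndarray, rvec: np.ndarray, tvec: np.ndarray):
        """Project Nx3 world points through pose + distortion to pixels."""
        R = Rotation.from_rotvec(rvec).as_matrix()
        cam = pts_world @ R.T + tvec
        x = cam[:, 0] / cam[:, 2]
        y = cam[:, 1] / cam[:, 2]
        xd, yd = self.distort_normalised(x, y)
        u, v = self.to_pixels(xd, yd)
        return np.column_stack([u, v])


@dataclass
class CheckerboardSpec:
    """A physical checkerboard: counted in squares, measured in mm.

    A board of ``squares_rows x squares_cols`` squares exposes an inner-corner
    grid of ``(squares_rows - 1) x (squares_cols - 1)`` detectable points.
    """

    squares_rows: int = 5
    squares_cols: int = 8
    square_size_mm: float = 50.0

    def __post_init__(self) -> None:
        if self.squares_rows < 2 or self.squares_cols < 2:
            raise ContractError("board needs at least 2x2 squares")
        if self.square_size_mm <= 0:
            raise ContractError("square size must be positive")

    @property
    def inner_rows(self) -> int:
        return self.squares_rows - 1

    @property
    def inner_cols(self) -> int:
        return self.squares_cols - 1

    @property
    def n_corners(self) -> int:
        return self.inner_rows * self.inner_cols

    def object_points(self) -> np.ndarray:
        """Inner-corner world coordinates (mm) in row-major board order, Z=0."""
        jj, ii = np.meshgrid(np.arange(self.inner_cols), np.arange(self.inner_rows))
        pts = np.zeros((self.n_corners, 3))
        pts[:, 0] = jj.ravel() * self.square_size_mm
        pts[:, 1] = ii.ravel() * self.square_size_mm
        return pts


@dataclass
class CalibrationResult:
    model: CameraModel
    per_image_reproj_err_px: list
    extrinsics: list = field(default_factory=list)  # (rvec, tvec) per view

    @property
    def mean_reproj_err_px(self) -> float:
        return float(np.mean(self.per_image_reproj_err_px))


# ---------------------------------------------------------------------------
# Corner detection
# ---------------------------------------------------------------------------


def _order_grid(points: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Order scattered grid corners row-major, top-left first.

    Works for near-planar views with modest perspective: points are rotated
    into their principal frame, split into rows by gaps along the minor axis,
    then each row is sorted along the major axis.
    """
    pts = points.astype(float)
    c = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - c)
    axes = vt  # row 0 = major (columns direction for wide boards)
    proj = (pts - c) @ axes.T
    if cols < rows:  # major axis should run along the longer grid dimension
        proj = proj[:, ::-1]
    order = np.argsort(proj[:, 1], kind="stable")
    rows_out = []
    for r in range(rows):
        chunk = order[r * cols:(r + 1) * cols]
        chunk = chunk[np.argsort(proj[chunk, 0], kind="stable")]
        rows_out.append(chunk)
    idx = np.concatenate(rows_out)
    out = pts[idx]
    # enforce right-handed labelling (col direction x row direction > 0 in
    # image coords) so the grid is a physical board pose, never a mirror
    grid = out.reshape(rows, cols, 2)
    v_col = grid[0, -1] - grid[0, 0]
    v_row = grid[-1, 0] - grid[0, 0]
    if v_col[0] * v_row[1] - v_col[1] * v_row[0] < 0:
        grid = grid[:, ::-1]
    out = grid.reshape(-1, 2)
    # deterministic orientation: first corner is the lexicographically
    # smaller of (first, last) in image coordinates
    first, last = out[0], out[-1]
    if (last[1], last[0]) < (first[1], first[0]):
        out = out[::-1].copy()
    return np.ascontiguousarray(out)


def detect_corners(image: BandImage, spec: CheckerboardSpec) -> np.ndarray:
    """Detect the inner checkerboard corners to sub-pixel accuracy.

    Returns an ``(n_corners, 2)`` array of ``(x, y)`` pixel positions in
    row-major board order.  Raises :class:`DetectionError` when the full grid
    cannot be found (blank frame, occluded board, wrong spec).
    """
    img = image.pixels.astype(float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.size == 0 or np.nanstd(img) < 1e-9:
        raise DetectionError("no checkerboard found (constant image)")
    img = (img - np.nanmin(img)) / max(np.nanmax(img) - np.nanmin(img), 1e-12)

    n = spec.n_corners
    response = corner_harris(img, sigma=2.0)
    # saddle-point corners: strong response; keep the n strongest well-spaced
    peaks = corner_peaks(response, min_distance=5, threshold_rel=0.05, num_peaks=n)
    if len(peaks) < n:
        raise DetectionError(
            f"expected {n} corners, found {len(peaks)}"
        )
    sub = corner_subpix(img, peaks, window_size=11)
    bad = ~np.isfinite(sub).all(axis=1)
    sub[bad] = peaks[bad]
    pts_xy = sub[:, ::-1]  # (row, col) -> (x, y)
    return _order_grid(pts_xy, spec.inner_rows, spec.inner_cols)


# ---------------------------------------------------------------------------
# Homography / Zhang bootstrap
# ---------------------------------------------------------------------------


def _dlt_homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Normalised DLT homography src (Nx2, board mm) -> dst (Nx2, px)."""

    def normalise(p):
        c = p.mean(axis=0)
        scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(p - c, axis=1)), 1e-12)
        T = np.array([[scale, 0, -scale * c[0]], [0, scale, -scale * c[1]], [0, 0, 1]])
        q = (p - c) * scale
        return q, T

    s, Ts = normalise(src)
    d, Td = normalise(dst)
    n = len(src)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:2] = s
    A[0::2, 2] = 1
    A[0::2, 6:8] = -d[:, [0]] * s
    A[0::2, 8] = -d[:, 0]
    A[1::2, 3:5] = s
    A[1::2, 5] = 1
    A[1::2, 6:8] = -d[:, [1]] * s
    A[1::2, 8] = -d[:, 1]
    _, _, vt = np.linalg.svd(A)
    H = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ H @ Ts
    return H / H[2, 2]


def _zhang_intrinsics(homographies: Sequence[np.ndarray], image_size) -> tuple:
    """Closed-form fx, fy, cx, cy from planar homographies (zero skew)."""

    def v(H, i, j):
        return np.array([
            H[0, i] * H[0, j],
            H[0, i] * H[1, j] + H[1, i] * H[0, j],
            H[1, i] * H[1, j],
            H[2, i] * H[0, j] + H[0, i] * H[2, j],
            H[2, i] * H[1, j] + H[1, i] * H[2, j],
            H[2, i] * H[2, j],
        ])

    rows = []
    for H in homographies:
        rows.append(v(H, 0, 1))
        rows.append(v(H, 0, 0) - v(H, 1, 1))
    V = np.array(rows)
    _, _, vt = np.linalg.svd(V)
    b = vt[-1]
    B11, B12, B22, B13, B23, B33 = b
    try:
        cy = (B12 * B13 - B11 * B23) / (B11 * B22 - B12 ** 2)
        lam = B33 - (B13 ** 2 + cy * (B12 * B13 - B11 * B23)) / B11
        fx = np.sqrt(lam / B11)
        fy = np.sqrt(lam * B11 / (B11 * B22 - B12 ** 2))
        cx = -B13 * fx ** 2 / lam
        if not all(np.isfinite([fx, fy, cx, cy])) or fx <= 0 or fy <= 0:
            raise ValueError
    except (ValueError, FloatingPointError, ZeroDivisionError):
        # fall back to a sensible guess centred on the frame
        w, h = image_size
        fx = fy = 1.2 * max(w, h)
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    return float(fx), float(fy), float(cx), float(cy)


def _extrinsics_from_h(K: np.ndarray, H: np.ndarray) -> tuple:
    """Factor a board homography into an (rvec, tvec) pose."""
    Kinv = np.linalg.inv(K)
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 1.0 / np.linalg.norm(Kinv @ h1)
    r1 = lam * (Kinv @ h1)
    r2 = lam * (Kinv @ h2)
    r3 = np.cross(r1, r2)
    R = np.column_stack([r1, r2, r3])
    u, _, vt = np.linalg.svd(R)  # nearest rotation
    R = u @ vt
    if np.linalg.det(R) < 0:
        R = u @ np.diag([1, 1, -1]) @ vt
    t = lam * (Kinv @ h3)
    if t[2] < 0:  # board must sit in front of the camera
        t = -t
        R = np.column_stack([-R[:, 0], -R[:, 1], R[:, 2]])
    return Rotation.from_matrix(R).as_rotvec(), t


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------


def calibrate(
    corner_sets: Sequence[np.ndarray],
    spec: CheckerboardSpec,
    image_size,
    band: str = "nir",
    n_radial_coeffs: int = 2,
) -> CalibrationResult:
    """Fit intrinsics + radial distortion from detected corner sets.

    Parameters
    ----------
    corner_sets:
        One ``(n_corners, 2)`` array of (x, y) pixel corners per view, in
        row-major board order (as produced by :func:`detect_corners`).
    spec:
        Physical board description.
    image_size:
        ``(width, height)`` of the calibrated frames in pixels.
    n_radial_coeffs:
        How many radial terms to estimate (1-3).  The default fits k1 and k2
        and pins k3 at zero: a checkerboard rarely covers enough off-axis
        radius to identify the r^6 term, which otherwise trades off against
        k1/k2 without improving the fit.

    Returns the fitted :class:`CameraModel` together with per-view and mean
    reprojection errors.  At least three views with distinct poses are
    required; near-identical poses trigger a conditioning warning.
    """
    if not 1 <= n_radial_coeffs <= 3:
        raise ContractError("n_radial_coeffs must be 1, 2 or 3")
    corner_sets = [np.asarray(c, dtype=float) for c in corner_sets]
    if len(corner_sets) < 3:
        raise InsufficientDataError(
            f"planar calibration needs >= 3 views, got {len(corner_sets)}"
        )
    obj = spec.object_points()
    for i, c in enumerate(corner_sets):
        if c.shape != (spec.n_corners, 2):
            raise ContractError(
                f"view {i}: expected {spec.n_corners} corners, got {c.shape}"
            )

    homs = [_dlt_homography(obj[:, :2], c) for c in corner_sets]
    spread = np.std([H / np.linalg.norm(H) for H in homs], axis=0).max()
    if spread < 1e-6:
        warnings.warn("calibration views have near-identical poses; "
                      "intrinsics are poorly conditioned", stacklevel=2)

    fx, fy, cx, cy = _zhang_intrinsics(homs, image_size)
    K = np.array([[fx, 0, cx], [0, fy, cy], [0, 0, 1]])
    poses = [_extrinsics_from_h(K, H) for H in homs]

    n_views = len(corner_sets)
    nk = n_radial_coeffs
    head = 4 + nk
    p0 = np.concatenate(
        [[fx, fy, cx, cy], np.zeros(nk)]
        + [np.concatenate([rv, tv]) for rv, tv in poses]
    )
    targets = np.concatenate([c.ravel() for c in corner_sets])

    def unpack(p):
        ks = [0.0, 0.0, 0.0]
        ks[:nk] = list(p[4:head])
        model = CameraModel(p[0], p[1], p[2], p[3], ks[0], ks[1], ks[2], band=band)
        views = [(p[head + 6 * i: head + 3 + 6 * i],
                  p[head + 3 + 6 * i: head + 6 + 6 * i])
                 for i in range(n_views)]
        return model, views

    def residuals(p):
        model, views = unpack(p)
        pred = np.concatenate(
            [model.project(obj, rv, tv).ravel() for rv, tv in views]
        )
        return pred - targets

    sol = least_squares(residuals, p0, method="lm", xtol=1e-12, ftol=1e-12)
    model, views = unpack(sol.x)

    per_img = []
    for c, (rv, tv) in zip(corner_sets, views):
        pred = model.project(obj, rv, tv)
        per_img.append(float(np.mean(np.linalg.norm(pred - c, axis=1))))
    return CalibrationResult(model, per_img, [
        (np.asarray(rv).copy(), np.asarray(tv).copy()) for rv, tv in views
    ])


# ---------------------------------------------------------------------------
# Undistortion
# ---------------------------------------------------------------------------


def undistort(image: BandImage, model: CameraModel) -> BandImage:
    """Resample a distorted frame onto the ideal (distortion-free) grid.

    Each output pixel is mapped through the forward radial model to its
    location in the distorted input and sampled bilinearly; NaN input pixels
    propagate to NaN.  With all distortion coefficients zero the mapping is
    the identity.
    """
    if model.band != image.band:
        raise ContractError(
            f"model band {model.band!r} does not match image band {image.band!r}"
        )
    h, w = image.grid
    vv, uu = np.mgrid[0:h, 0:w].astype(float)
    x, y = model.from_pixels(uu, vv)
    xd, yd = model.distort_normalised(x, y)
    ud, vd = model.to_pixels(xd, yd)

    def sample(plane):
        return ndimage.map_coordinates(
            plane.astype(float), [vd, ud], order=1, mode="constant", cval=np.nan
        )

    if image.pixels.ndim == 3:
        out = np.dstack([sample(image.pixels[:, :, c]) for c in range(3)])
    else:
        out = sample(image.pixels)
    return BandImage(out, image.band, image.units)
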