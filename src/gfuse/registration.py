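"""Two-stage thermal-to-multispectral image registration.

The thermal and multispectral cameras share a mount but not a sensor plane,
so the thermal frame must be projected into the multispectral field of view.
Alignment runs in two stages, mirroring how a practitioner registers
cross-modality frames:

coarse
    Feature-based rigid/similarity estimation from corner correspondences on
    a geometric cut-out target (shapes in a corflute sheet in front of a warm
    wall — visible as intensity corners in both modalities), robustified with
    M-estimator Sample Consensus (MSAC).  The coarse transform depends only
    on the camera geometry, so it is estimated once per imaging session.

fine
    Intensity-based affine refinement driven by Mattes mutual information
    under a seeded (1+1) evolutionary optimiser, absorbing per-capture
    residuals such as canopy movement between the two exposures.

Transforms use homogeneous 3x3 matrices acting on column vectors
``(x, y, 1)``: ``x`` = column, ``y`` = row, angles counter-clockwise in the
``(x, y)`` plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

from .raster import BandImage, ContractError, DetectionError, RegistrationError

__all__ = [
    "Transform2D",
    "FeatureMatchSet",
    "RegistrationReport",
    "compose",
    "detect_target_corners",
    "estimate_coarse",
    "fine_register",
    "mattes_mmi",
    "warp",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Transform algebra
# ---------------------------------------------------------------------------

_KINDS = ("translation", "rigid", "similarity", "affine")


@dataclass
class Transform2D:
    """3x3 homogeneous planar transform with a kind tag."""

    matrix: np.ndarray
    kind: str = "affine"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ContractError("transform matrix must be 3x3")
        if not np.allclose(self.matrix[2], [0.0, 0.0, 1.0], atol=1e-9):
            raise ContractError("bottom row of a planar transform must be [0 0 1]")
        if self.kind not in _KINDS:
            raise ContractError(f"unknown transform kind {self.kind!r}")
        if self.kind == "rigid":
            A = self.matrix[:2, :2]
            if not (np.allclose(A @ A.T, np.eye(2), atol=1e-6)
                    and np.linalg.det(A) > 0):
                raise ContractError("rigid transform must have a rotation block")

    @classmethod
    def identity(cls, kind: str = "rigid") -> "Transform2D":
        return cls(np.eye(3), kind)

    def apply(self, pts: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        homo = np.column_stack([pts, np.ones(len(pts))])
        out = homo @ self.matrix.T
        return out[:, :2] / out[:, [2]]

    def inverse(self) -> "Transform2D":
        return Transform2D(np.linalg.inv(self.matrix), self.kind)

    def __matmul__(self, other: "Transform2D") -> "Transform2D":
        kind = "affine" if {self.kind, other.kind} - {"translation", "rigid"} else "rigid"
        if self.kind == other.kind:
            kind = self.kind
        return Transform2D(self.matrix @ other.matrix, kind)


def compose(tx: float = 0.0, ty: float = 0.0, q: float = 0.0,
            shx: float = 0.0, shy: float = 0.0,
            sx: float = 1.0, sy: float = 1.0) -> Transform2D:
    """Build a transform from translation, rotation, shear and scale parts.

    The four elementary matrices are concatenated as ``S @ Sh @ R @ T``
    (translation applied first, scale last).  ``q`` is the counter-clockwise
    rotation angle in radians.  The kind tag reflects the most general
    non-identity component.
    """
    if sx == 0 or sy == 0:
        raise ContractError("scale factors must be nonzero")
    T = np.array([[1, 0, tx], [0, 1, ty], [0, 0, 1]], dtype=float)
    c, s = np.cos(q), np.sin(q)
    R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    Sh = np.array([[1, shx, 0], [shy, 1, 0], [0, 0, 1]], dtype=float)
    S = np.array([[sx, 0, 0], [0, sy, 0], [0, 0, 1]], dtype=float)
    M = S @ Sh @ R @ T
    if shx or shy or sx != 1 or sy != 1:
        kind = "affine"
    elif q:
        kind = "rigid"
    else:
        kind = "translation" if (tx or ty) else "rigid"
    return Transform2D(M, kind)


# ---------------------------------------------------------------------------
# Feature matching containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureMatchSet:
    """Paired keypoints between a fixed and a moving frame."""

    fixed_pts: np.ndarray
    moving_pts: np.ndarray
    inlier_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.fixed_pts = np.atleast_2d(np.asarray(self.fixed_pts, dtype=float))
        self.moving_pts = np.atleast_2d(np.asarray(self.moving_pts, dtype=float))
        if len(self.fixed_pts) != len(self.moving_pts):
            raise ContractError("fixed and moving point lists must have equal length")
        if self.inlier_mask is None:
            self.inlier_mask = np.ones(len(self.fixed_pts), dtype=bool)

    def __len__(self) -> int:
        return len(self.fixed_pts)


@dataclass
class RegistrationReport:
    coarse: Transform2D
    fine: Transform2D
    mmi: float
    residual_px: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.mmi):
            raise ContractError("mmi must be finite")
        if self.residual_px < 0:
            raise ContractError("residual must be non-negative")


# ---------------------------------------------------------------------------
# Target corner detection
# ---------------------------------------------------------------------------


def detect_target_corners(image: BandImage, max_corners: int = 64,
                          min_distance: int = 8) -> np.ndarray:
    """Find corner keypoints of the high-contrast cut-out target.

    Works identically on optical and thermal renders of the scene (Harris
    responds to the contrast magnitude, not its sign).  Returns an
    ``(n, 2)`` array of (x, y) keypoints ordered by corner response,
    strongest first.  Fewer than four corners raises
    :class:`DetectionError`.
    """
    from skimage.feature import corner_harris, corner_peaks, corner_subpix

    img = image.pixels.astype(float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    rng = np.nanmax(img) - np.nanmin(img)
    if not np.isfinite(rng) or rng < 1e-9:
        raise DetectionError("no target corners found (constant image)")
    img = (img - np.nanmin(img)) / rng

    response = corner_harris(img, sigma=2.0)
    peaks = corner_peaks(response, min_distance=min_distance,
                         threshold_rel=0.02, num_peaks=max_corners)
    if len(peaks) < 4:
        raise DetectionError(f"found only {len(peaks)} target corners (need >= 4)")
    scores = response[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(scores)[::-1]
    peaks = peaks[order]
    sub = corner_subpix(img, peaks, window_size=9)
    bad = ~np.isfinite(sub).all(axis=1)
    sub[bad] = peaks[bad]
    return sub[:, ::-1]  # (row, col) -> (x, y)


def match_corners(fixed_pts: np.ndarray, moving_pts: np.ndarray,
                  max_norm_dist: float = 0.15) -> FeatureMatchSet:
    """Pair corners across modalities by shape, not by detection order.

    Both point sets are normalised to zero mean and unit RMS radius — which
    cancels the translation and scale between the two frames — and then
    paired by mutual nearest neighbours within ``max_norm_dist`` of the
    normalised radius.  Adequate for the rig's near-similarity geometry;
    gross detections simply fail to pair and MSAC handles the rest.
    """
    f = np.atleast_2d(np.asarray(fixed_pts, dtype=float))
    m = np.atleast_2d(np.asarray(moving_pts, dtype=float))

    def normalise(p):
        c = p.mean(axis=0)
        s = np.sqrt(np.mean(np.sum((p - c) ** 2, axis=1)))
        return (p - c) / max(s, 1e-12)

    fn, mn = normalise(f), normalise(m)
    d = np.linalg.norm(fn[:, None, :] - mn[None, :, :], axis=2)
    fi, mi = [], []
    for i in range(len(fn)):
        j = int(np.argmin(d[i]))
        if np.argmin(d[:, j]) == i and d[i, j] < max_norm_dist:
            fi.append(i)
            mi.append(j)
    if len(fi) < 2:
        raise RegistrationError("could not pair target corners across modalities")
    return FeatureMatchSet(f[fi], m[mi])


# ---------------------------------------------------------------------------
# Coarse estimation (MSAC)
# ---------------------------------------------------------------------------


def _fit_similarity(src: np.ndarray, dst: np.ndarray, rigid: bool) -> np.ndarray:
    """Least-squares similarity/rigid transform src -> dst (Umeyama)."""
    mu_s = src.mean(axis=0)
    mu_d = dst.mean(axis=0)
    sc = src - mu_s
    dc = dst - mu_d
    cov = dc.T @ sc / len(src)
    u, d, vt = np.linalg.svd(cov)
    sgn = np.sign(np.linalg.det(u @ vt))
    D = np.diag([1.0, sgn])
    R = u @ D @ vt
    if rigid:
        scale = 1.0
    else:
        var_s = (sc ** 2).sum() / len(src)
        scale = np.trace(np.diag(d) @ D) / max(var_s, 1e-12)
    t = mu_d - scale * R @ mu_s
    M = np.eye(3)
    M[:2, :2] = scale * R
    M[:2, 2] = t
    return M


def estimate_coarse(
    matches: FeatureMatchSet,
    kind: str = "rigid",
    msac_threshold_px: float = 2.0,
    max_trials: int = 500,
    min_inlier_frac: float = 0.5,
    seed: int = 0,
) -> Transform2D:
    """Robust rigid/similarity transform moving -> fixed via MSAC.

    MSAC scores each hypothesis by the truncated squared residual
    ``sum(min(r_i^2, threshold^2))`` — unlike plain RANSAC, inliers still pay
    their residual, so the lowest-cost model is also the best-fitting one.
    The winning model is refit on its inliers and ``matches.inlier_mask`` is
    updated in place.
    """
    if kind not in ("rigid", "similarity"):
        raise ContractError("coarse estimation supports rigid or similarity kinds")
    n = len(matches)
    min_n = 2 if kind in ("rigid", "similarity") else 3
    if n < min_n:
        raise ContractError(f"need >= {min_n} point pairs, got {n}")
    src = matches.moving_pts
    dst = matches.fixed_pts
    rigid = kind == "rigid"

    rng = np.random.default_rng(seed)
    thr2 = msac_threshold_px ** 2
    best_cost = np.inf
    best_M = None
    trials = min(max_trials, 1 if n == min_n else max_trials)
    for _ in range(trials):
        idx = rng.choice(n, size=min_n, replace=False) if n > min_n else np.arange(n)
        M = _fit_similarity(src[idx], dst[idx], rigid)
        pred = src @ M[:2, :2].T + M[:2, 2]
        r2 = ((pred - dst) ** 2).sum(axis=1)
        cost = np.minimum(r2, thr2).sum()
        if cost < best_cost - 1e-15:
            best_cost = cost
            best_M = M
    pred = src @ best_M[:2, :2].T + best_M[:2, 2]
    r2 = ((pred - dst) ** 2).sum(axis=1)
    inliers = r2 < thr2
    if inliers.sum() < max(min_n, min_inlier_frac * n):
        raise RegistrationError(
            f"MSAC found no consensus ({inliers.sum()}/{n} inliers)"
        )
    M = _fit_similarity(src[inliers], dst[inliers], rigid)
    matches.inlier_mask = inliers
    return Transform2D(M, kind)


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------


def mattes_mmi(a: BandImage, b: BandImage, bins: int = 64) -> float:
    """Mutual information (bits) between two co-gridded images.

    Intensities of the jointly defined pixels are quantised into ``bins``
    equal-width bins over each image's own range and MI is read off the joint
    histogram.  Higher values mean the two modalities are better aligned.
    MI(X, X) equals the entropy of X's binned histogram, and the measure is
    invariant to monotone intensity remappings up to binning error — which is
    what makes it usable across modalities (thermal vs reflectance).
    """
    if a.grid != b.grid:
        raise ContractError(f"grids differ: {a.grid} vs {b.grid}")
    if bins < 2:
        raise ContractError("need at least 2 bins")
    joint_def = a.defined() & b.defined()
    if not joint_def.any():
        raise ContractError("images share no defined pixels")
    av = np.asarray(a.pixels, dtype=float)[joint_def]
    bv = np.asarray(b.pixels, dtype=float)[joint_def] if b.pixels.ndim == 2 else None
    if b.pixels.ndim == 3:
        bv = b.pixels.astype(float).mean(axis=2)[joint_def]
    if a.pixels.ndim == 3:
        av = a.pixels.astype(float).mean(axis=2)[joint_def]
    for v, name in ((av, "a"), (bv, "b")):
        if np.ptp(v) <= 0:
            raise ContractError(f"image {name} has < 2 distinct defined values")
    hist, _, _ = np.histogram2d(av, bv, bins=bins)
    pxy = hist / hist.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


# ---------------------------------------------------------------------------
# Warping
# ---------------------------------------------------------------------------


def warp(image: BandImage, t: Transform2D, out_size) -> BandImage:
    """Project ``image`` through ``t`` onto a ``(width, height)`` output grid.

    ``t`` maps moving-image coordinates to output coordinates; resampling is
    inverse-mapped bilinear, and anything falling outside the source frame
    (or onto NaN source pixels) becomes nodata.
    """
    if abs(np.linalg.det(t.matrix)) < 1e-12:
        raise ContractError("transform matrix is singular")
    w, h = int(out_size[0]), int(out_size[1])
    inv = np.linalg.inv(t.matrix)
    vv, uu = np.mgrid[0:h, 0:w].astype(float)
    src = np.dstack([uu, vv, np.ones_like(uu)]) @ inv.T
    sx = src[:, :, 0] / src[:, :, 2]
    sy = src[:, :, 1] / src[:, :, 2]

    def sample(plane):
        return ndimage.map_coordinates(
            plane.astype(float), [sy, sx], order=1, mode="constant", cval=np.nan
        )

    if image.pixels.ndim == 3:
        out = np.dstack([sample(image.pixels[:, :, c]) for c in range(3)])
    else:
        out = sample(image.pixels)
    if image.units in ("dn8", "dn16"):
        # bilinear output is a convex combination; clamp float round-off
        hi = 255.0 if image.units == "dn8" else 65535.0
        out = np.clip(out, 0.0, hi)
    return BandImage(out, image.band, image.units)


# ---------------------------------------------------------------------------
# Fine registration: (1+1) evolutionary optimiser on Mattes MI
# ---------------------------------------------------------------------------


def _overlap_fraction(fixed: BandImage, moving: BandImage, t: Transform2D) -> float:
    h, w = fixed.grid
    moved = warp(moving, t, (w, h))
    both = fixed.defined() & moved.defined()
    denom = max(int(fixed.defined().sum()), 1)
    return both.sum() / denom


def fine_register(
    fixed: BandImage,
    moving: BandImage,
    init: Transform2D,
    bins: int = 64,
    initial_radius: float = 6.25e-3,
    growth: float = 1.05,
    shrink: float = 0.5 ** 0.25,
    max_iterations: int = 200,
    seed: int = 42,
) -> Transform2D:
    """Refine an initial transform by maximising Mattes mutual information.

    A (1+1) evolutionary strategy perturbs the affine parameters
    ``(tx, ty, q, shx, shy, log sx, log sy)`` with Gaussian steps whose
    radius grows by ``growth`` on success and contracts by ``shrink`` on
    failure.  Parameter scales are tied to the fixed frame size so the
    initial radius corresponds to roughly one-pixel translation steps.  The
    search is elitist, so the returned transform never scores below the
    initial one, and it is fully reproducible for a given ``seed``.
    """
    h, w = fixed.grid
    if _overlap_fraction(fixed, moving, init) < 0.5:
        raise RegistrationError("initial transform overlaps < 50% of the fixed frame")

    fixed_grey = fixed
    if fixed.pixels.ndim == 3:
        fixed_grey = BandImage(fixed.pixels.astype(float).mean(axis=2),
                               "green_rgb", "unitless")

    def params_to_transform(p):
        return compose(tx=p[0], ty=p[1], q=p[2], shx=p[3], shy=p[4],
                       sx=np.exp(p[5]), sy=np.exp(p[6]))

    base = init.matrix

    def score(p):
        t = Transform2D(params_to_transform(p).matrix @ base)
        moved = warp(moving, t, (w, h))
        both = fixed_grey.defined() & moved.defined()
        if both.sum() < 0.25 * fixed_grey.defined().sum():
            return -np.inf
        fsub = BandImage(np.where(both, fixed_grey.pixels, np.nan), fixed_grey.band)
        msub = BandImage(np.where(both, moved.pixels, np.nan), moved.band)
        try:
            return mattes_mmi(fsub, msub, bins=bins)
        except ContractError:
            return -np.inf

    # parameter scales: full frame for translation, ~0.3 rad rotation, 0.1
    # shear / log-scale — so the initial radius is ~1-2 px of translation and
    # sub-degree rotation, and all parameters converge at comparable rates
    scales = np.array([w, h, 0.3, 0.1, 0.1, 0.1, 0.1])
    rng = np.random.default_rng(seed)
    p = np.zeros(7)
    best = score(p)
    radius = initial_radius
    for _ in range(max_iterations):
        cand = p + radius * scales * rng.standard_normal(7)
        val = score(cand)
        if val > best:
            p, best = cand, val
            radius *= growth
        else:
            radius *= shrink
    return Transform2D(params_to_transform(p).matrix @ base, "affine")
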