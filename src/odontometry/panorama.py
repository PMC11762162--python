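"""Dental arch curve fitting and panoramic reprojection.

The arch curve is recovered from the mean axial projection of the volume:
bright pixels are selected by Otsu's threshold, a per-column weighted centroid
gives one support point per frontal position, and a weighted quartic
polynomial fit resampled at equal arc length yields the ordered curve points
r(c) with buccally-oriented unit normals n(c).  The panoramic image P(c, z)
averages trilinear samples of the volume along each normal over t in [-w, w];
the discrete mean keeps panoramic intensities on the input scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

__all__ = [
    "ArchCurve",
    "PanoramicImage",
    "mean_axial_projection",
    "fit_arch_curve",
    "extract_panoramic",
    "project_point_to_panoramic",
]


@dataclass
class ArchCurve:
    """Ordered arch points in axial-plane voxel coordinates with unit normals."""

    points: np.ndarray  # (Nc, 2) (x, y)
    normals: np.ndarray  # (Nc, 2), unit, buccal (away from curve centroid)
    arc_step: float = 1.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        if len(self.points) < 2:
            raise ValueError("curve needs at least 2 points")
        if np.any(np.all(np.diff(self.points, axis=0) == 0, axis=1)):
            raise ValueError("consecutive curve points must be distinct")
        norms = np.linalg.norm(self.normals, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("normals must have unit length")
        tangents = np.gradient(self.points, axis=0)
        dots = np.abs(np.sum(tangents * self.normals, axis=1)) / np.linalg.norm(tangents, axis=1)
        # perpendicularity within a small tolerance away from the endpoints
        if len(self.points) > 8 and np.any(dots[2:-2] > 0.2):
            raise ValueError("normals must be perpendicular to the local tangent")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class PanoramicImage:
    """2D reprojection P(c, z): width = number of curve points, height = Nz."""

    values: np.ndarray  # (Nc, Nz)
    curve: ArchCurve
    half_width: float  # w, voxels

    @property
    def width(self) -> int:
        return self.values.shape[0]

    @property
    def height(self) -> int:
        return self.values.shape[1]


def mean_axial_projection(volume) -> np.ndarray:
    """Mean intensity over z per (x, y) pixel."""
    if volume.intensities.size == 0:
        raise ValueError("empty volume")
    return volume.intensities.mean(axis=2)


def _resample_equal_arc(pts: np.ndarray, n_points: int | None):
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate(([0.0], np.cumsum(seg)))
    total = arc[-1]
    if n_points is None:
        n_points = max(int(round(total)), 8)
    s_eq = np.linspace(0.0, total, n_points)
    out = np.stack([np.interp(s_eq, arc, pts[:, 0]), np.interp(s_eq, arc, pts[:, 1])], axis=1)
    return out, total


def _normals_of(points: np.ndarray) -> np.ndarray:
    tang = np.gradient(points, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normals = np.stack([tang[:, 1], -tang[:, 0]], axis=1)
    # orient buccally: away from the centroid of the curve, per point (the
    # open ends can kink, which would otherwise flip the sign locally)
    centroid = points.mean(axis=0)
    sign = np.sign(np.sum((points - centroid) * normals, axis=1))
    sign[sign == 0] = 1.0
    return normals * sign[:, None]


def fit_arch_curve(
    projection: np.ndarray,
    n_points: int | None = None,
    threshold: float | None = None,
    degree: int = 4,
    refine_iters: int = 5,
    refine_half: float = 18.0,
) -> ArchCurve:
    """Fit the arch curve to a bright arch-shaped region of a 2D projection.

    Initialisation: per-column weighted y-centroid of supra-threshold pixels
    and a weighted quartic polynomial fit, resampled at equal arc length.
    Column centroids are biased where the arch runs steeply (the posterior
    ends), so the fit is refined iteratively: each curve point moves to the
    midpoint of the bright band sampled along its local normal — exact for a
    band symmetric about the arch — and the quartic is refit through the
    moved points.  Refitting (rather than free-form point updates) keeps the
    curve smooth at the arch scale: per-tooth structure cannot wiggle it and
    the open ends cannot hook into the last molars.  Raises
    ``ValueError("arch not found")`` when fewer than 5 columns support the
    fit.
    """
    proj = np.asarray(projection, dtype=float)
    if threshold is None:
        finite = proj[np.isfinite(proj)]
        if finite.size == 0 or finite.max() <= finite.min():
            raise ValueError("arch not found: blank projection")
        threshold = threshold_otsu(finite)
    bright = np.clip(proj - threshold, 0.0, None)
    mass = bright.sum(axis=1)
    support = np.nonzero(mass > 0)[0]
    if len(support) < 5:
        raise ValueError("arch not found: fewer than 5 supporting columns")
    ys = np.arange(proj.shape[1], dtype=float)
    cent = (bright[support] * ys[None, :]).sum(axis=1) / mass[support]
    coeff = np.polyfit(support.astype(float), cent, deg=degree, w=np.sqrt(mass[support]))
    xs = np.linspace(support.min(), support.max(), 2000)
    points, total = _resample_equal_arc(np.stack([xs, np.poly1d(coeff)(xs)], axis=1), None)
    on_thresh = 0.05 * max(float(bright.max()), 1e-12)
    for _ in range(max(refine_iters, 0)):
        normals = _normals_of(points)
        ts = np.arange(-refine_half, refine_half + 1e-9, 0.5)
        pos = points[:, None, :] + ts[None, :, None] * normals[:, None, :]
        vals = ndimage.map_coordinates(
            bright, [pos[..., 0].ravel(), pos[..., 1].ravel()], order=1, mode="constant", cval=0.0
        ).reshape(len(points), len(ts))
        on = vals > on_thresh
        any_on = on.any(axis=1)
        first = np.argmax(on, axis=1)
        last = len(ts) - 1 - np.argmax(on[:, ::-1], axis=1)
        shift = np.where(any_on, 0.5 * (ts[first] + ts[last]), 0.0)
        moved = points + shift[:, None] * normals
        wts = on.sum(axis=1).astype(float)
        keep = wts > 0
        if keep.sum() < 5:
            break
        coeff = np.polyfit(moved[keep, 0], moved[keep, 1], deg=degree, w=np.sqrt(wts[keep]))
        xs = np.linspace(moved[keep, 0].min(), moved[keep, 0].max(), 2000)
        points, total = _resample_equal_arc(np.stack([xs, np.poly1d(coeff)(xs)], axis=1), None)
    points, total = _resample_equal_arc(points, n_points)
    normals = _normals_of(points)
    return ArchCurve(points, normals, arc_step=float(total / max(len(points) - 1, 1)))


def extract_panoramic(volume, curve: ArchCurve, w: float = 15.0, K: int | None = None) -> PanoramicImage:
    """Sample P(c, z) = mean over t in {-w..w} of X(r(c) + t n(c), z).

    2K+1 trilinear samples per column position; out-of-grid samples are
    excluded from the mean.
    """
    if w < 1:
        raise ValueError("w must be >= 1 voxel")
    if K is None:
        K = max(int(round(w)), 1)
    ts = np.linspace(-w, w, 2 * K + 1)
    nx, ny, nz = volume.shape
    # sample positions: (Nc, 2K+1, 2)
    pos = curve.points[:, None, :] + ts[None, :, None] * curve.normals[:, None, :]
    valid = (
        (pos[..., 0] >= 0) & (pos[..., 0] <= nx - 1) & (pos[..., 1] >= 0) & (pos[..., 1] <= ny - 1)
    )
    if not valid.any():
        raise ValueError("curve (with offsets) lies entirely outside the grid")
    zc = np.arange(nz, dtype=float)
    Nc, S = pos.shape[:2]
    cx = np.broadcast_to(pos[..., 0, None], (Nc, S, nz)).ravel()
    cy = np.broadcast_to(pos[..., 1, None], (Nc, S, nz)).ravel()
    cz = np.broadcast_to(zc[None, None, :], (Nc, S, nz)).ravel()
    samples = ndimage.map_coordinates(
        volume.intensities.astype(float), np.stack([cx, cy, cz]), order=1, mode="constant", cval=0.0
    ).reshape(Nc, S, nz)
    vmask = np.broadcast_to(valid[..., None], (Nc, S, nz))
    counts = vmask.sum(axis=1)
    sums = np.where(vmask, samples, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        P = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return PanoramicImage(P, curve, float(w))


def project_point_to_panoramic(point, curve: ArchCurve, w: float):
    """Map a 3D voxel coordinate to panoramic (c, z), or None beyond w.

    c is the index of the nearest curve point in the axial plane; z passes
    through unchanged.
    """
    p = np.asarray(point, dtype=float)
    d = np.linalg.norm(curve.points - p[None, :2], axis=1)
    c = int(np.argmin(d))
    if d[c] > w:
        return None
    return c, float(p[2])
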