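"""Per-jaw tooth detection, adaptive midline estimation and FDI numbering.

After jaw alignment, each jaw's maximum intensity projection (MIP) along the
axial axis is segmented into individual teeth.  The jaw profile — the outer
(buccal/anterior) boundary of the closed MIP foreground — supplies both the
midline (the anterior boundary run farthest from the boundary centroid) and
an arc-length ordering, from which teeth are numbered 1 (central incisor) to
6 (first molar) per side.  A scan-derived depth map can stand in for the MIP,
so the same chain serves both CBCT and plaster-model scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import DepthMap, VoxelVolume
from .jaws import Region2D, segment_bright_regions

__all__ = [
    "MipImage",
    "ToothDetection",
    "JawProfile",
    "align_jaw",
    "estimate_inclination",
    "compute_mip",
    "surface_depth_map",
    "detect_teeth_on_mip",
    "extract_jaw_profile",
    "estimate_midline",
    "assign_fdi",
    "identification_from_depthmap",
]


@dataclass
class MipImage:
    """Axial maximum intensity projection with its arg-max depth map.

    For the upper jaw the volume is z-flipped before projection so that depth
    is always occlusal-surface-first; ``flipped`` records this.
    """

    values: np.ndarray  # (Nx, Ny)
    depth: DepthMap  # arg-max z (smallest index attaining the max)
    jaw: str = "lower"
    flipped: bool = False
    cell_size: tuple = (0.3, 0.3)


@dataclass
class ToothDetection:
    mask: np.ndarray
    box: tuple  # (x0, y0, h, w): w along x (axis 0), h along y (axis 1)
    center: np.ndarray  # box centre (x0 + w/2, y0 + h/2)
    jaw: str = ""
    side: str | None = None
    fdi: int | None = None
    flags: list = field(default_factory=list)

    @staticmethod
    def box_center(box: tuple) -> np.ndarray:
        x0, y0, h, w = box
        return np.array([x0 + w / 2.0, y0 + h / 2.0])


@dataclass
class JawProfile:
    """Open outer-boundary curve of a jaw MIP with midline information."""

    boundary: np.ndarray  # (M, 2) ordered points, left distal -> right distal
    centroid: np.ndarray  # mean of boundary points
    p_mid: np.ndarray | None = None
    axis: np.ndarray | None = None  # unit vector p_mid -> centroid (posterior)

    def arc_lengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.boundary, axis=0), axis=1)
        return np.concatenate(([0.0], np.cumsum(seg)))

    def nearest_index(self, point) -> int:
        return int(np.argmin(np.linalg.norm(self.boundary - np.asarray(point)[None, :], axis=1)))

    def tangent_at(self, index: int, half_arc: float = 12.0) -> np.ndarray:
        """Local tangent from a secant spanning ``half_arc`` boundary length
        each way — wide enough to average out pixel jags and per-tooth
        bulges while staying inside the neighbouring teeth."""
        arcs = self.arc_lengths()
        lo = int(np.searchsorted(arcs, arcs[index] - half_arc))
        hi = int(np.searchsorted(arcs, arcs[index] + half_arc)) - 1
        lo = max(min(lo, index - 1), 0)
        hi = min(max(hi, index + 1), len(self.boundary) - 1)
        t = self.boundary[hi] - self.boundary[lo]
        n = np.linalg.norm(t)
        if n == 0:
            raise ValueError("degenerate boundary tangent")
        return t / n


# ---------------------------------------------------------------------------
# alignment


def align_jaw(volume: VoxelVolume, alpha_deg: float) -> VoxelVolume:
    """Undo the mandibular inclination: rotate by -alpha about the frontal axis."""
    if not np.isfinite(alpha_deg):
        raise ValueError("alpha must be finite")
    if abs(alpha_deg) > 60:
        raise ValueError(f"implausible inclination angle {alpha_deg} deg (|alpha| <= 60)")
    if alpha_deg == 0:
        return volume
    rotated = ndimage.rotate(
        volume.intensities, -alpha_deg, axes=(1, 2), reshape=False, order=1, mode="constant", cval=0.0
    )
    return VoxelVolume(rotated.astype(volume.intensities.dtype), volume.spacing, volume.origin)


def estimate_inclination(teeth_mask: np.ndarray, spacing) -> float:
    """Fallback inclination estimate: tilt of the teeth principal plane.

    Fits a plane to the teeth voxels (PCA); the returned angle is the
    rotation about the frontal axis taking the axial plane onto that plane.
    """
    idx = np.argwhere(teeth_mask).astype(float) * np.asarray(spacing)[None, :]
    if len(idx) < 10:
        raise ValueError("too few teeth voxels to estimate inclination")
    c = idx - idx.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    n = vt[-1]
    if n[2] < 0:
        n = -n
    return float(np.degrees(np.arctan2(-n[1], n[2])))


# ---------------------------------------------------------------------------
# MIP and depth


def compute_mip(volume: VoxelVolume, jaw: str = "lower") -> MipImage:
    """Per-pixel max over z with the smallest z attaining it as depth."""
    if volume.intensities.size == 0:
        raise ValueError("empty volume")
    data = volume.intensities
    flipped = jaw == "upper"
    if flipped:
        data = data[:, :, ::-1]
    mip = data.max(axis=2)
    depth_idx = data.argmax(axis=2).astype(float)
    depth = DepthMap(
        depth_idx,
        np.ones_like(mip, dtype=bool),
        cell_size=(volume.spacing[0], volume.spacing[1]),
        origin=(volume.origin[0], volume.origin[1]),
        z_units="voxel",
        z_scale=volume.spacing[2],
    )
    return MipImage(mip, depth, jaw=jaw, flipped=flipped, cell_size=(volume.spacing[0], volume.spacing[1]))


def surface_depth_map(mask_volume: np.ndarray, volume: VoxelVolume, jaw: str) -> DepthMap:
    """Occlusal-surface z per (x, y) column of a binary jaw mask.

    The occlusal surface faces the antagonist jaw: max z for the lower jaw,
    min z for the upper.  Values are voxel z indices of the original grid.
    """
    any_col = mask_volume.any(axis=2)
    nz = mask_volume.shape[2]
    zs = np.arange(nz)
    if jaw == "lower":
        vals = np.where(mask_volume, zs[None, None, :], -1).max(axis=2).astype(float)
    else:
        vals = np.where(mask_volume, zs[None, None, :], nz + 1).min(axis=2).astype(float)
    vals[~any_col] = 0.0
    return DepthMap(
        vals,
        any_col,
        cell_size=(volume.spacing[0], volume.spacing[1]),
        origin=(volume.origin[0], volume.origin[1]),
        z_units="voxel",
        z_scale=volume.spacing[2],
    )


# ---------------------------------------------------------------------------
# detection


def detect_teeth_on_mip(
    mip: MipImage,
    detector=None,
    threshold: float | None = 0.0,
    min_spacing_mm: float = 5.0,
    min_area_mm2: float = 6.0,
    opening_radius: int = 2,
    foreground: np.ndarray | None = None,
) -> list[ToothDetection]:
    """Segment individual teeth on a (masked) MIP.

    The reference detector thresholds the MIP, opens away thin artefacts
    (metal streaks), and splits fused teeth by distance-transform watershed
    with peak separation at least the minimum tooth spacing.
    """
    cell = mip.cell_size[0]
    if detector is None:
        regions = segment_bright_regions(
            mip.values,
            threshold=threshold,
            opening_radius=opening_radius,
            min_area=max(int(min_area_mm2 / cell**2), 4),
            split_min_distance=min_spacing_mm / cell,
            foreground=foreground,
        )
    else:
        regions = detector(mip.values)
    # fragments closer than the minimal anatomical tooth spacing cannot be
    # distinct teeth (a cracked footprint, e.g. from unassigned slices) —
    # merge them into one detection
    merge_dist = 0.8 * min_spacing_mm / cell
    merged = True
    while merged and len(regions) > 1:
        merged = False
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                if np.linalg.norm(regions[i].centroid - regions[j].centroid) < merge_dist:
                    a, b = regions[i], regions[j]
                    mask = a.mask | b.mask
                    idx = np.argwhere(mask)
                    i0, j0 = idx.min(axis=0)
                    i1, j1 = idx.max(axis=0)
                    box = (int(i0), int(j0), int(j1 - j0 + 1), int(i1 - i0 + 1))
                    regions[i] = Region2D(mask, box, idx.mean(axis=0))
                    del regions[j]
                    merged = True
                    break
            if merged:
                break
    dets = []
    for r in regions:
        # Region2D box is (i0, j0, h, w); keep the same reading here
        dets.append(ToothDetection(r.mask, r.box, ToothDetection.box_center(r.box), jaw=mip.jaw))
    if not dets:
        raise ValueError("no teeth on MIP")
    return dets


# ---------------------------------------------------------------------------
# jaw profile and midline


def extract_jaw_profile(
    mip: MipImage,
    threshold: float | None = 0.0,
    closing_radius_mm: float = 1.5,
    n_rays: int = 900,
    foreground: np.ndarray | None = None,
) -> JawProfile:
    """Trace the outer (buccal/anterior) border of the closed MIP foreground.

    Morphological closing bridges inter-tooth gaps; the outer border is then
    traced by casting rays from the region centroid and keeping the farthest
    foreground pixel per ray — an open curve running from one distal end to
    the other (the posterior gap carries no foreground).
    """
    if foreground is None:
        foreground = mip.values > (threshold if threshold is not None else 0.0)
    cols = np.nonzero(foreground.any(axis=1))[0]
    if len(cols) < 3:
        raise ValueError("jaw profile: foreground in fewer than 3 columns")
    cell = mip.cell_size[0]
    from skimage.morphology import disk

    r = max(int(round(closing_radius_mm / cell)), 1)
    closed = ndimage.binary_closing(foreground, structure=disk(r), border_value=0)
    closed = ndimage.binary_fill_holes(closed)
    cy = np.array(ndimage.center_of_mass(closed))
    angles = np.linspace(0.0, 2.0 * np.pi, n_rays, endpoint=False)
    rad = np.arange(1.0, float(max(closed.shape)) * 1.5, 0.5)
    px = cy[0] + rad[None, :] * np.cos(angles)[:, None]
    py = cy[1] + rad[None, :] * np.sin(angles)[:, None]
    inside = (px >= 0) & (px <= closed.shape[0] - 1) & (py >= 0) & (py <= closed.shape[1] - 1)
    hit = np.zeros_like(px, dtype=bool)
    ii = np.clip(np.round(px).astype(int), 0, closed.shape[0] - 1)
    jj = np.clip(np.round(py).astype(int), 0, closed.shape[1] - 1)
    hit = closed[ii, jj] & inside
    far_idx = np.where(hit.any(axis=1), hit.shape[1] - 1 - np.argmax(hit[:, ::-1], axis=1), -1)
    good = far_idx >= 0
    if good.sum() < 3:
        raise ValueError("jaw profile: arch band not found")
    # order rays so the largest angular run of misses separates the two ends
    miss = ~good
    if miss.any():
        runs = []
        idx = np.arange(n_rays)
        m = miss.astype(int)
        # find the longest circular run of misses
        best_len, best_end, cur = 0, 0, 0
        for k in range(2 * n_rays):
            if m[k % n_rays]:
                cur += 1
                if cur > best_len:
                    best_len, best_end = cur, k
            else:
                cur = 0
        start = (best_end + 1) % n_rays
        order = [(start + k) % n_rays for k in range(n_rays)]
    else:
        order = list(range(n_rays))
    pts = []
    for k in order:
        if good[k]:
            pts.append([px[k, far_idx[k]], py[k, far_idx[k]]])
    boundary = np.array(pts)
    centroid = boundary.mean(axis=0)
    return JawProfile(boundary, centroid)


def estimate_midline(
    profile: JawProfile,
    delta_d: float = 8.0,
    anterior_fraction: float = 1 / 3,
    center: np.ndarray | None = None,
) -> JawProfile:
    """Locate the adaptive midline on the jaw profile.

    Within the anterior (middle-arc-length) segment of the boundary, the
    points whose distance to the reference centre is within ``delta_d`` of
    the maximum form a contiguous run; their coordinate mean is the midline
    point.  The midline axis is the unit vector from that point through the
    centre.

    When ``center`` is given, the criterion is the literal distance to that
    point.  By default the distance is taken to a centre placed at infinity
    behind the arch — i.e. the projection of each boundary point onto the
    arch's anterior symmetry direction (the minor principal axis of the
    boundary, oriented away from the distal ends).  The projection form is
    insensitive to where exactly the posterior centre sits, which matters on
    wide, shallow arches whose flat incisor face would otherwise tie against
    its own corners.
    """
    if len(profile.boundary) < 3:
        raise ValueError("boundary needs at least 3 points")
    arcs = profile.arc_lengths()
    total = arcs[-1]
    lo = (0.5 - anterior_fraction / 2.0) * total
    hi = (0.5 + anterior_fraction / 2.0) * total
    cand = np.nonzero((arcs >= lo) & (arcs <= hi))[0]
    if len(cand) == 0:
        cand = np.arange(len(profile.boundary))
    if center is not None:
        center = np.asarray(center, dtype=float)
        d = np.linalg.norm(profile.boundary[cand] - center[None, :], axis=1)
    else:
        b = profile.boundary - profile.boundary.mean(axis=0)
        _, _, vt = np.linalg.svd(b, full_matrices=False)
        anterior = vt[-1]  # minor principal axis
        ends_mid = 0.5 * (profile.boundary[0] + profile.boundary[-1])
        apex_dir = profile.boundary[cand[len(cand) // 2]] - ends_mid
        if np.dot(anterior, apex_dir) < 0:
            anterior = -anterior
        center = None
        d = profile.boundary[cand] @ anterior
    imax = int(np.argmax(d))
    keep = d >= d[imax] - delta_d
    # contiguous run [c_min, c_max] containing the maximum
    c_min = imax
    while c_min > 0 and keep[c_min - 1]:
        c_min -= 1
    c_max = imax
    while c_max < len(cand) - 1 and keep[c_max + 1]:
        c_max += 1
    run = cand[c_min : c_max + 1]
    p_mid = profile.boundary[run].mean(axis=0)
    axis = -anterior if center is None else (center - p_mid) / np.linalg.norm(center - p_mid)
    return JawProfile(profile.boundary, profile.centroid, p_mid, axis)


def fixed_midline(profile: JawProfile, center_x: float | None = None) -> JawProfile:
    """Baseline: midline fixed in the image (scanner) frame.

    The midline is the mid-sagittal column of the image (``center_x``; the
    boundary centroid's column when not given), with the sagittal (+y)
    direction as axis.  It does not adapt to the jaw's actual orientation —
    the non-adaptive comparator for the adaptive estimator.
    """
    if center_x is None:
        center_x = float(profile.centroid[0])
    axis = np.array([0.0, 1.0])
    i = int(np.argmin(np.abs(profile.boundary[:, 0] - center_x)))
    p_mid = np.array([center_x, profile.boundary[i, 1]])
    return JawProfile(profile.boundary, profile.centroid, p_mid, axis)


# ---------------------------------------------------------------------------
# numbering


def assign_fdi(detections: list[ToothDetection], profile: JawProfile) -> list[ToothDetection]:
    """Sign detections left/right of the midline axis and number 1..6 per side.

    Teeth are ordered by the arc-length position of their projection onto
    the jaw boundary, nearest to the midline first.  More than six teeth on
    a side leaves the extras unnumbered (flagged); fewer than six is flagged
    as a shortfall but numbering proceeds.
    """
    if profile.p_mid is None or profile.axis is None:
        raise ValueError("profile carries no midline; run estimate_midline first")
    arcs = profile.arc_lengths()
    mid_arc = arcs[profile.nearest_index(profile.p_mid)]
    ax = profile.axis
    sides: dict[str, list] = {"left": [], "right": []}
    for det in detections:
        rel = det.center - profile.p_mid
        cross = ax[0] * rel[1] - ax[1] * rel[0]
        det.side = "left" if cross > 0 else "right"
        arc = arcs[profile.nearest_index(det.center)]
        sides[det.side].append((abs(arc - mid_arc), det))
    for side, items in sides.items():
        items.sort(key=lambda t: t[0])
        for k, (_, det) in enumerate(items, start=1):
            if k <= 6:
                det.fdi = k
            else:
                det.fdi = None
                det.flags.append("unnumbered: more than 6 teeth on side")
        if len(items) < 6:
            for _, det in items:
                det.flags.append(f"shortfall: only {len(items)} teeth on {side} side")
    return detections


def identification_from_depthmap(
    depth: DepthMap,
    jaw: str = "upper",
    detector=None,
    min_spacing_mm: float = 5.0,
    delta_d_mm: float = 2.4,
    adaptive: bool = True,
):
    """Run the detection → profile → midline → numbering chain on a depth map.

    The depth map (teeth-only, from the scan path) replaces the MIP; the
    validity mask is the foreground.  Returns (detections, profile, MipImage
    stand-in).
    """
    if not depth.valid.any():
        raise ValueError("no teeth on MIP: empty depth map")
    base = float(depth.values[depth.valid].min())
    img = np.where(depth.valid, depth.values - base + 1.0, 0.0)
    mip = MipImage(img, depth, jaw=jaw, cell_size=depth.cell_size)
    cell = depth.cell_size[0]
    dets = detect_teeth_on_mip(
        mip, detector=detector, min_spacing_mm=min_spacing_mm, foreground=depth.valid.copy()
    )
    profile = extract_jaw_profile(mip, foreground=depth.valid.copy())
    if adaptive:
        profile = estimate_midline(profile, delta_d=delta_d_mm / cell)
    else:
        profile = fixed_midline(profile)
    dets = assign_fdi(dets, profile)
    return dets, profile, mip
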