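"""Upper/lower jaw separation by sagittal-slice segmentation fused with the panoramic view.

Each constant-y slice is segmented into per-tooth binary masks; every mask is
reduced to the centre point of its bounding box, projected into the panoramic
frame, and assigned to the upper or lower panoramic tooth region.  The
boundary between the regions is a least-squares line through the midpoints of
vertically adjacent upper/lower mask-centroid pairs.

The slice segmenter is a behavioural contract (any callable mapping a 2D
image to disjoint masks).  The reference implementation is classical:
threshold at the teeth-intensity level, morphological opening, connected
components, and an h-maxima-seeded distance-transform watershed that splits
fused components (e.g. upper and lower crowns in a closed bite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk, h_maxima
from skimage.segmentation import watershed

from .panorama import ArchCurve, PanoramicImage, project_point_to_panoramic

__all__ = [
    "SliceMask",
    "PanoramicToothMasks",
    "JawAssignment",
    "Region2D",
    "bright_tail_otsu",
    "segment_bright_regions",
    "reference_slice_segmenter",
    "slice_masks_of_volume",
    "representative_point",
    "split_panoramic_masks",
    "assign_jaws",
]


@dataclass
class SliceMask:
    """A segmented tooth cross-section in one sagittal slice.

    ``box`` is (x0, z0, h, w) with w the extent along x and h along z — the
    only self-consistent reading of the centre-point formula.  The
    representative point is the box centre (x0 + w/2, s, z0 + h/2).
    """

    slice_index: int
    mask: np.ndarray  # 2D bool, (Nx, Nz)
    box: tuple  # (x0, z0, h, w)

    def __post_init__(self) -> None:
        if not self.mask.any():
            raise ValueError("mask must be nonempty")

    @property
    def point(self) -> np.ndarray:
        return representative_point(self.box, self.slice_index)


@dataclass
class Region2D:
    """A generic segmented region on a 2D image (pano or MIP)."""

    mask: np.ndarray
    box: tuple  # (i0, j0, h, w): w along axis 0, h along axis 1
    centroid: np.ndarray  # (i, j) float


@dataclass
class PanoramicToothMasks:
    upper: list
    lower: list
    line: tuple  # (slope a, intercept b): z = a*c + b

    def side_of(self, c: float, z: float) -> str:
        a, b = self.line
        return "upper" if z > a * c + b else "lower"


@dataclass
class JawAssignment:
    upper: np.ndarray  # bool volume
    lower: np.ndarray
    unassigned: int = 0


def representative_point(box: tuple, s: int) -> np.ndarray:
    """Centre point (x0 + w/2, s, z0 + h/2) of a slice-mask bounding box."""
    x0, z0, h, w = box
    if h <= 0 or w <= 0:
        raise ValueError(f"box extents must be positive, got h={h}, w={w}")
    return np.array([x0 + w / 2.0, float(s), z0 + h / 2.0])


def bright_tail_otsu(values: np.ndarray) -> float:
    """Two-stage Otsu: threshold the bright tail above the global split.

    Separates teeth from bone when the histogram also contains soft tissue
    and background.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    t1 = threshold_otsu(v)
    tail = v[v > t1]
    if tail.size < 2 or tail.max() <= tail.min():
        return t1
    return float(threshold_otsu(tail))


def _split_component(mask: np.ndarray, min_distance: float, h: float) -> list[np.ndarray]:
    """Split a fused component at distance-transform waists.

    Seeds are the h-maxima of the euclidean distance transform; maxima closer
    than ``min_distance`` are merged, the seed count is capped by how many
    teeth the component's extent can hold, and a split only happens when at
    least two seeds survive.
    """
    dist = ndimage.distance_transform_edt(mask)
    peaks = h_maxima(dist, h)
    lab, n = ndimage.label(peaks)
    if n < 2:
        return [mask]
    idx = np.argwhere(mask)
    ext = float((idx.max(axis=0) - idx.min(axis=0) + 1).max())
    n_max = max(2, int(round(ext / (1.4 * min_distance))))
    cents = np.array(ndimage.center_of_mass(peaks, lab, range(1, n + 1)))
    order = np.argsort(-np.array(ndimage.maximum(dist, lab, range(1, n + 1))))
    kept: list[np.ndarray] = []
    for i in order:
        if len(kept) >= n_max:
            break
        if all(np.linalg.norm(cents[i] - c) >= min_distance for c in kept):
            kept.append(cents[i])
    if len(kept) < 2:
        return [mask]
    markers = np.zeros(mask.shape, dtype=int)
    for k, c in enumerate(kept, start=1):
        markers[int(round(c[0])), int(round(c[1]))] = k
    ws = watershed(-dist, markers, mask=mask)
    return [ws == k for k in range(1, len(kept) + 1) if np.any(ws == k)]


def segment_bright_regions(
    image: np.ndarray,
    threshold: float | None = None,
    opening_radius: int = 1,
    min_area: int = 6,
    split_min_distance: float = 10.0,
    split_h: float = 3.0,
    split_gate: float | None = None,
    foreground: np.ndarray | None = None,
) -> list[Region2D]:
    """Reference 2D segmenter: threshold, opening, components, watershed split.

    Returned masks are disjoint.  ``foreground`` overrides thresholding when
    a validity mask (e.g. of a depth map) already defines the foreground.
    A component is only considered for watershed splitting when its bounding
    box exceeds ``split_gate`` pixels (default 2.4x the peak separation) —
    single teeth are smaller than that, fused ones are not.
    """
    img = np.asarray(image, dtype=float)
    if split_gate is None:
        split_gate = 2.4 * split_min_distance
    if foreground is None:
        if threshold is None:
            threshold = bright_tail_otsu(img)
        foreground = img > threshold
    if opening_radius > 0:
        foreground = ndimage.binary_opening(foreground, structure=disk(opening_radius))
    lab, n = ndimage.label(foreground)
    regions: list[Region2D] = []
    for i in range(1, n + 1):
        comp = lab == i
        if comp.sum() < min_area:
            continue
        idx0 = np.argwhere(comp)
        ext = (idx0.max(axis=0) - idx0.min(axis=0) + 1).max()
        parts = (
            _split_component(comp, split_min_distance, split_h) if ext > split_gate else [comp]
        )
        for part in parts:
            if part.sum() < min_area:
                continue
            idx = np.argwhere(part)
            i0, j0 = idx.min(axis=0)
            i1, j1 = idx.max(axis=0)
            box = (int(i0), int(j0), int(j1 - j0 + 1), int(i1 - i0 + 1))
            regions.append(Region2D(part, box, idx.mean(axis=0)))
    return regions


def reference_slice_segmenter(
    image: np.ndarray,
    threshold: float | None = None,
    opening_radius: int = 1,
    min_area: int = 6,
    split_min_distance: float = 12.0,
    split_h: float = 3.0,
) -> list[Region2D]:
    """Classical per-slice tooth segmenter (SliceSegmenter contract)."""
    return segment_bright_regions(
        image,
        threshold=threshold,
        opening_radius=opening_radius,
        min_area=min_area,
        split_min_distance=split_min_distance,
        split_h=split_h,
    )


def slice_masks_of_volume(volume, threshold: float | None = None, segmenter=None) -> list[SliceMask]:
    """Run the slice segmenter over every sagittal (constant-y) slice."""
    if threshold is None:
        threshold = bright_tail_otsu(volume.intensities)
    if segmenter is None:
        segmenter = lambda img: reference_slice_segmenter(img, threshold=threshold)
    out: list[SliceMask] = []
    for s in range(volume.shape[1]):
        for reg in segmenter(volume.intensities[:, s, :]):
            out.append(SliceMask(s, reg.mask, reg.box))
    return out


def _two_means_1d(values: np.ndarray, max_iter: int = 64):
    """Deterministic 2-means on a 1D array (init: min and max)."""
    v = np.asarray(values, dtype=float)
    c = np.array([v.min(), v.max()])
    if c[0] == c[1]:
        raise ValueError("cannot establish jaw boundary: degenerate centroid values")
    for _ in range(max_iter):
        assign = np.abs(v[:, None] - c[None, :]).argmin(axis=1)
        if not (assign == 0).any() or not (assign == 1).any():
            raise ValueError("cannot establish jaw boundary: one cluster empty")
        new = np.array([v[assign == 0].mean(), v[assign == 1].mean()])
        if np.allclose(new, c):
            break
        c = new
    return assign, c


def split_panoramic_masks(
    pano: PanoramicImage,
    segmenter=None,
    threshold: float | None = None,
) -> PanoramicToothMasks:
    """Segment teeth on the panoramic image and split them into jaws.

    Mask centroids are clustered into two groups by their z coordinate
    (deterministic 2-means); the boundary is the least-squares line through
    midpoints of vertically adjacent upper/lower centroid pairs.
    """
    if segmenter is None:
        regions = segment_bright_regions(
            pano.values, threshold=threshold, split_min_distance=12.0, split_h=3.0
        )
    else:
        regions = segmenter(pano.values)
    if len(regions) < 2:
        raise ValueError("cannot establish jaw boundary: fewer than 2 panoramic masks")
    cz = np.array([r.centroid[1] for r in regions])
    assign, cents = _two_means_1d(cz)
    hi = int(np.argmax(cents))  # anatomically the upper jaw sits at larger z
    upper = [r for r, a in zip(regions, assign) if a == hi]
    lower = [r for r, a in zip(regions, assign) if a != hi]
    ux = np.array([r.centroid[0] for r in upper])
    mids = []
    for r in lower:
        j = int(np.argmin(np.abs(ux - r.centroid[0])))
        mids.append(((upper[j].centroid[0] + r.centroid[0]) / 2.0, (upper[j].centroid[1] + r.centroid[1]) / 2.0))
    mids = np.array(mids)
    if len(mids) >= 2 and np.ptp(mids[:, 0]) > 1e-9:
        a, b = np.polyfit(mids[:, 0], mids[:, 1], 1)
    else:
        a, b = 0.0, float(mids[:, 1].mean())
    masks = PanoramicToothMasks([], [], (float(a), float(b)))
    for r in regions:
        side = "upper" if r.centroid[1] > a * r.centroid[0] + b else "lower"
        (masks.upper if side == "upper" else masks.lower).append(r)
    if not masks.upper or not masks.lower:
        raise ValueError("cannot establish jaw boundary: one side empty")
    return masks


def assign_jaws(
    slice_masks: list[SliceMask],
    pano_masks: PanoramicToothMasks,
    curve: ArchCurve,
    w: float,
    volume_shape: tuple,
    tau: float = 3.0,
) -> JawAssignment:
    """Collect slice masks into the upper/lower 3D label volumes.

    Each mask's representative point is projected onto the panoramic frame;
    the (rounded) pixel is looked up in the upper/lower mask sets, falling
    back to the nearest mask within ``tau`` panoramic pixels.  Points beyond
    the curve half-width (or farther than tau from any mask) stay unassigned.
    """
    nc = len(curve)
    nz = volume_shape[2]
    up2d = np.zeros((nc, nz), dtype=bool)
    lo2d = np.zeros((nc, nz), dtype=bool)
    for r in pano_masks.upper:
        up2d |= r.mask
    for r in pano_masks.lower:
        lo2d |= r.mask
    d_up, idx_up = ndimage.distance_transform_edt(~up2d, return_indices=True)
    d_lo, idx_lo = ndimage.distance_transform_edt(~lo2d, return_indices=True)

    upper = np.zeros(volume_shape, dtype=bool)
    lower = np.zeros(volume_shape, dtype=bool)
    unassigned = 0
    for sm in slice_masks:
        proj = project_point_to_panoramic(sm.point, curve, w)
        if proj is None:
            unassigned += 1
            continue
        c = int(np.clip(round(proj[0]), 0, nc - 1))
        z = int(np.clip(round(proj[1]), 0, nz - 1))
        if up2d[c, z]:
            side = "upper"
        elif lo2d[c, z]:
            side = "lower"
        elif min(d_up[c, z], d_lo[c, z]) <= tau:
            side = "upper" if d_up[c, z] <= d_lo[c, z] else "lower"
        else:
            unassigned += 1
            continue
        tgt = upper if side == "upper" else lower
        tgt[:, sm.slice_index, :] |= sm.mask
    # a voxel reached from both sides is resolved by removing it from both:
    # the hard invariant is that the upper and lower volumes never intersect
    both = upper & lower
    if both.any():
        upper &= ~both
        lower &= ~both
    return JawAssignment(upper, lower, unassigned)
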