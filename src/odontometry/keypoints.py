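"""Landmark detection, 3D lifting, mesio-distal widths, cusp tips and arch widths.

Per numbered tooth, a region of interest is cropped from the MIP (or scan
depth map) and the mesial/distal landmarks are located along the tooth's
local mesio-distal axis — the tangent of the arch boundary at the tooth's
projection.  Landmarks are lifted to 3D via the occlusal depth map, and the
tooth width is the 3D Euclidean distance between the pair.

Landmark backends are pluggable through a coarse-to-fine cascade contract:
each stage refines the estimate on a window that shrinks geometrically around
the previous estimate.  The repository ships a geometric reference backend
(mask extreme points, no training) and a small trainable regressor stage
fitted by minibatch stochastic gradient descent with momentum on a
mean-squared landmark error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks
from skimage.transform import resize

from .identify import JawProfile, ToothDetection
from .io import DepthMap

__all__ = [
    "ToothRoi",
    "LandmarkPair",
    "CascadeDetector",
    "ReferenceStage",
    "TrainedStage",
    "TrainingConfig",
    "crop_tooth_roi",
    "reference_landmark_backend",
    "run_cascade",
    "train_cascade_stage",
    "mse_loss",
    "sgdm_step",
    "lift_to_3d",
    "mesiodistal_width",
    "cusp_tips",
    "arch_widths",
]


@dataclass
class ToothRoi:
    """Crop around one numbered tooth with its local mesio-distal frame.

    ``origin`` maps crop to global pixel coordinates (global = origin +
    local).  ``axis`` is the unit mesio-distal direction (arch-boundary
    tangent); ``mesial_sign`` = +1 when +axis points toward the midline.
    """

    image: np.ndarray  # cropped intensity / depth image
    mask: np.ndarray  # cropped tooth mask
    origin: np.ndarray  # (2,) int
    axis: np.ndarray  # unit 2-vector
    mesial_sign: float
    cell_mm: float
    detection: ToothDetection | None = None
    #: sub-pixel outward offset of landmark estimates. Voxel masks sample
    #: solidity at cell centres and are inward-biased by half a cell per
    #: side (offset 0.5); point-raster masks mark any hit and are already
    #: unbiased (offset 0.0).
    edge_offset: float = 0.5

    def to_global(self, p):
        return np.asarray(p, dtype=float) + self.origin

    def to_local(self, p):
        return np.asarray(p, dtype=float) - self.origin

    @property
    def mesial_dir(self) -> np.ndarray:
        return self.axis * self.mesial_sign


@dataclass
class LandmarkPair:
    """Mesial/distal landmarks in global 2D pixels, optionally lifted to mm."""

    mesial_2d: np.ndarray
    distal_2d: np.ndarray
    mesial_3d: np.ndarray | None = None
    distal_3d: np.ndarray | None = None
    backend: str = "reference"
    cascade_depth: int = 1
    flags: list = field(default_factory=list)


@dataclass
class TrainingConfig:
    """Minibatch SGDM hyper-parameters (defaults follow common practice for
    small landmark regressors: batch 64, learning rate 1e-3, momentum 0.95)."""

    batch_size: int = 64
    learning_rate: float = 1e-3
    momentum: float = 0.95
    epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")


# ---------------------------------------------------------------------------
# ROI


def tooth_axes(detections) -> dict:
    """Per-tooth mesio-distal axes from neighbouring detection centres.

    Numbered detections are ordered along the arch (right 6 → right 1 →
    left 1 → left 6); each tooth's axis is the chord through its two
    neighbours' centres — for a parabolic arch that chord is exactly
    parallel to the tangent at the tooth, and it is rigid-motion
    equivariant.  Returns {id(detection): (axis, mesial_sign)}.
    """

    def _key(det):
        return det.fdi if det.side == "left" else -det.fdi

    seq = sorted([d for d in detections if d.fdi is not None], key=_key)
    out = {}
    for i, det in enumerate(seq):
        a = seq[max(i - 1, 0)].center
        b = seq[min(i + 1, len(seq) - 1)].center
        chord = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
        n = np.linalg.norm(chord)
        if n == 0:
            continue
        chord /= n
        # +chord walks right→left; the midline sits between the two blocks
        mesial_sign = 1.0 if det.side == "right" else -1.0
        out[id(det)] = (chord, mesial_sign)
    return out


def crop_tooth_roi(
    image: np.ndarray,
    detection: ToothDetection,
    profile: JawProfile,
    margin_mm: float = 1.5,
    cell_mm: float = 0.3,
    axis: np.ndarray | None = None,
    mesial_sign: float | None = None,
) -> ToothRoi:
    """Crop the detection box dilated by ``margin_mm``, clipped to the image.

    The local mesio-distal axis defaults to the arch-boundary tangent at the
    tooth's nearest boundary point (pass ``axis``/``mesial_sign`` from
    :func:`tooth_axes` for the more stable neighbour-chord estimate); the
    mesial sign points toward the midline along the boundary arc.
    """
    m = int(np.ceil(margin_mm / cell_mm))
    x0, y0, h, w = detection.box
    lo = np.maximum([x0 - m, y0 - m], 0)
    hi = np.minimum([x0 + w + m, y0 + h + m], image.shape)
    if np.any(lo >= hi):
        raise ValueError("tooth crop lies outside the image")
    sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]))
    if axis is None or mesial_sign is None:
        idx = profile.nearest_index(detection.center)
        axis = profile.tangent_at(idx)
        arcs = profile.arc_lengths()
        mid_idx = profile.nearest_index(profile.p_mid) if profile.p_mid is not None else 0
        # mesial = decreasing |arc - mid_arc|
        toward_mid = -1.0 if arcs[idx] > arcs[mid_idx] else 1.0
        mesial_sign = toward_mid
    return ToothRoi(
        image[sl].copy(),
        detection.mask[sl].copy(),
        np.array(lo, dtype=int),
        np.asarray(axis, dtype=float),
        float(mesial_sign),
        cell_mm,
        detection,
    )


# ---------------------------------------------------------------------------
# landmark backends


def _extreme_point(mask: np.ndarray, direction: np.ndarray, edge_offset: float = 0.5) -> np.ndarray:
    """Sub-pixel extreme of a mask along a direction.

    Pixels within half a pixel of the maximal projection are averaged in the
    perpendicular coordinate, and the point is pushed ``edge_offset`` pixels
    outward so that an axis-aligned rectangle (voxel-sampled) yields the
    midpoint of its edge.
    """
    pts = np.argwhere(mask).astype(float)
    if len(pts) < 3:
        raise ValueError("degenerate mask (<3 pixels)")
    proj = pts @ direction
    keep = proj >= proj.max() - 0.5
    edge = pts[keep].mean(axis=0)
    return edge + edge_offset * direction


def reference_landmark_backend(roi: ToothRoi) -> LandmarkPair:
    """Mask extreme points along the local mesio-distal axis (2D only)."""
    if not roi.mask.any():
        raise ValueError("degenerate mask (<3 pixels)")
    mes = _extreme_point(roi.mask, roi.mesial_dir, roi.edge_offset)
    dis = _extreme_point(roi.mask, -roi.mesial_dir, roi.edge_offset)
    return LandmarkPair(roi.to_global(mes), roi.to_global(dis), backend="reference")


class ReferenceStage:
    """Cascade stage wrapping the geometric extreme-point refiner."""

    name = "reference"

    def __init__(self, edge_offset: float = 0.5):
        self.edge_offset = edge_offset

    def predict(self, window_img, window_mask, axis, direction, which: str):
        return _extreme_point(window_mask, direction, self.edge_offset)


class TrainedStage:
    """Linear regressor on a resized, normalised crop (one landmark).

    Input: crop resized to ``input_size``; output: landmark position as a
    fraction of the window extent.  Trained by :func:`train_cascade_stage`.
    """

    name = "trained"
    input_size = (16, 16)

    def __init__(self, weights: np.ndarray, bias: np.ndarray):
        self.weights = weights
        self.bias = bias

    @staticmethod
    def featurize(img: np.ndarray) -> np.ndarray:
        f = resize(np.asarray(img, dtype=float), TrainedStage.input_size, anti_aliasing=True)
        peak = f.max()
        if peak > 0:
            f = f / peak
        return f.ravel()

    def predict(self, window_img, window_mask, axis, direction, which: str):
        rel = self.weights @ self.featurize(window_img) + self.bias
        return rel * (np.array(window_img.shape, dtype=float) - 1.0)


@dataclass
class CascadeDetector:
    """Ordered refinement stages with a geometric shrink factor per stage."""

    stages: list
    shrink: float = 0.6

    def __post_init__(self):
        if len(self.stages) < 1:
            raise ValueError("cascade needs at least one stage")
        if not (0 < self.shrink <= 1):
            raise ValueError("shrink must be in (0, 1]")


def _window(roi: ToothRoi, center: np.ndarray, size: np.ndarray):
    lo = np.maximum(np.round(center - size / 2.0).astype(int), 0)
    hi = np.minimum(lo + np.maximum(size.astype(int), 3), roi.image.shape)
    lo = np.maximum(hi - np.maximum(size.astype(int), 3), 0)
    sl = (slice(lo[0], hi[0]), slice(lo[1], hi[1]))
    return sl, lo


def run_cascade(detector: CascadeDetector, roi: ToothRoi) -> LandmarkPair:
    """Coarse-to-fine landmark refinement.

    Stage k operates on a window of ``shrink**k`` times the ROI size centred
    on the previous estimate (stage 0 sees the full ROI).  Estimates leaving
    the ROI are clamped to its boundary and flagged low-confidence.
    """
    roi_size = np.array(roi.image.shape, dtype=float)
    flags: list[str] = []
    results = {}
    for which, direction in (("mesial", roi.mesial_dir), ("distal", -roi.mesial_dir)):
        est = None
        for k, stage in enumerate(detector.stages):
            if k == 0:
                sl = (slice(0, roi.image.shape[0]), slice(0, roi.image.shape[1]))
                lo = np.zeros(2, dtype=int)
            else:
                size = roi_size * detector.shrink**k
                sl, lo = _window(roi, est, size)
            local = stage.predict(roi.image[sl], roi.mask[sl], roi.axis, direction, which)
            est = np.asarray(local, dtype=float) + lo
            out = np.clip(est, 0, roi_size - 1)
            if np.any(out != est):
                est = out
                flags.append(f"{which}: estimate clamped to ROI boundary")
        results[which] = roi.to_global(est)
    pair = LandmarkPair(
        results["mesial"],
        results["distal"],
        backend=detector.stages[-1].name,
        cascade_depth=len(detector.stages),
        flags=flags,
    )
    return pair


# ---------------------------------------------------------------------------
# training (minibatch SGDM on mean squared landmark error)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean squared error over all landmark coordinates."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    return float(np.mean((pred - target) ** 2))


def sgdm_step(theta, grad, velocity, learning_rate: float, momentum: float):
    """One stochastic-gradient-descent-with-momentum update.

    v_{t+1} = momentum * v_t + grad;  theta_{t+1} = theta_t - lr * v_{t+1}.
    With zero momentum this reduces to theta - lr * grad.
    """
    velocity = momentum * velocity + grad
    return theta - learning_rate * velocity, velocity


def train_cascade_stage(examples, config: TrainingConfig) -> TrainedStage:
    """Fit a :class:`TrainedStage` on (crop, true-landmark) examples.

    ``examples`` is a sequence of (image, landmark_xy) with the landmark in
    crop pixel coordinates.  The regressor predicts the landmark as a
    fraction of the crop extent; optimisation is seeded, minibatch SGDM on
    the mean squared error.
    """
    if len(examples) < config.batch_size:
        raise ValueError(
            f"need at least batch_size={config.batch_size} examples, got {len(examples)}"
        )
    rng = np.random.default_rng(config.seed)
    X = np.stack([TrainedStage.featurize(img) for img, _ in examples])
    Y = np.stack(
        [
            np.asarray(lm, dtype=float) / (np.array(img.shape, dtype=float) - 1.0)
            for img, lm in examples
        ]
    )
    n_feat = X.shape[1]
    W = rng.normal(0.0, 0.01, size=(2, n_feat))
    b = np.full(2, 0.5)
    vW = np.zeros_like(W)
    vb = np.zeros_like(b)
    n = len(X)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n - config.batch_size + 1, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = X[idx], Y[idx]
            pred = xb @ W.T + b
            err = pred - yb  # (m, 2)
            gW = 2.0 * err.T @ xb / err.size
            gb = 2.0 * err.sum(axis=0) / err.size
            W, vW = sgdm_step(W, gW, vW, config.learning_rate, config.momentum)
            b, vb = sgdm_step(b, gb, vb, config.learning_rate, config.momentum)
    return TrainedStage(W, b)


def stage_loss(stage: TrainedStage, examples) -> float:
    X = np.stack([TrainedStage.featurize(img) for img, _ in examples])
    Y = np.stack(
        [
            np.asarray(lm, dtype=float) / (np.array(img.shape, dtype=float) - 1.0)
            for img, lm in examples
        ]
    )
    return mse_loss(X @ stage.weights.T + stage.bias, Y)


# ---------------------------------------------------------------------------
# lifting and widths


def lift_to_3d(point2d, depth: DepthMap, search_radius: int = 3) -> np.ndarray:
    """Lift a global 2D pixel position to millimetres via the depth map.

    z comes from the nearest valid depth cell within ``search_radius`` cells;
    in-plane coordinates are converted through the depth grid's cell size and
    origin.
    """
    p = np.asarray(point2d, dtype=float)
    i, j = int(round(p[0])), int(round(p[1]))
    ni, nj = depth.values.shape
    if not (0 <= i < ni and 0 <= j < nj):
        raise ValueError("landmark outside depth-map bounds")
    best = None
    for r in range(search_radius + 1):
        ii0, ii1 = max(i - r, 0), min(i + r + 1, ni)
        jj0, jj1 = max(j - r, 0), min(j + r + 1, nj)
        sub = depth.valid[ii0:ii1, jj0:jj1]
        if sub.any():
            cand = np.argwhere(sub) + [ii0, jj0]
            d = np.linalg.norm(cand - [i, j], axis=1)
            k = int(np.argmin(d))
            best = cand[k]
            break
    if best is None:
        raise ValueError("landmark off tooth surface: no valid depth cell in range")
    z_mm = float(depth.values[best[0], best[1]]) * depth.z_scale
    return np.array(
        [
            depth.origin[0] + p[0] * depth.cell_size[0],
            depth.origin[1] + p[1] * depth.cell_size[1],
            z_mm,
        ]
    )


def mesiodistal_width(pair: LandmarkPair) -> float:
    """3D Euclidean distance between the lifted mesial and distal landmarks."""
    if pair.mesial_3d is None or pair.distal_3d is None:
        raise ValueError("both landmarks must be lifted to 3D first")
    return float(np.linalg.norm(np.asarray(pair.mesial_3d) - np.asarray(pair.distal_3d)))


def lift_pair(pair: LandmarkPair, depth: DepthMap, search_radius: int = 3) -> LandmarkPair:
    pair.mesial_3d = lift_to_3d(pair.mesial_2d, depth, search_radius)
    pair.distal_3d = lift_to_3d(pair.distal_2d, depth, search_radius)
    return pair


# ---------------------------------------------------------------------------
# cusp tips and arch widths


def profile_peaks(profile_values: np.ndarray, prominence: float):
    """Indices of local maxima with at least the given prominence."""
    vals = np.asarray(profile_values, dtype=float)
    peaks, _ = find_peaks(vals, prominence=prominence)
    return peaks


def cusp_tips(
    roi: ToothRoi,
    depth: DepthMap,
    pair: LandmarkPair,
    profile: JawProfile,
    fdi: int,
    prominence_mm: float = 0.5,
    molar_mesial_fraction: float = 0.25,
) -> dict:
    """Locate cusp tips on the bucco-lingual depth profile of one tooth.

    The 1D profile runs perpendicular to the mesio-distal axis through the
    landmark midpoint (for the first molar: through the point a quarter of
    the way from the mesial landmark, targeting the mesio-buccal cusp).
    Peaks above the prominence threshold are cusp candidates; the buccal tip
    is the peak on the side away from the arch centroid.  Canines have a
    single tip.
    """
    if fdi not in (3, 4, 6):
        raise ValueError("cusp tips are located on canine (3), 1st premolar (4) or 1st molar (6)")
    mes = np.asarray(pair.mesial_2d, dtype=float)
    dis = np.asarray(pair.distal_2d, dtype=float)
    anchor = mes + (dis - mes) * (molar_mesial_fraction if fdi == 6 else 0.5)
    perp = np.array([-roi.axis[1], roi.axis[0]])
    # orient toward buccal: away from the arch centroid
    if np.dot(perp, anchor - profile.centroid) < 0:
        perp = -perp
    half = max(roi.image.shape) * 0.75
    ts = np.arange(-half, half + 1e-9, 1.0)
    zvals = np.full(len(ts), np.nan)
    for k, t in enumerate(ts):
        q = anchor + t * perp
        i, j = int(round(q[0])), int(round(q[1]))
        if 0 <= i < depth.values.shape[0] and 0 <= j < depth.values.shape[1]:
            if depth.valid[i, j]:
                zvals[k] = depth.values[i, j] * depth.z_scale
    ok = np.isfinite(zvals)
    if ok.sum() < 3:
        raise ValueError("cusp not found: profile off the tooth surface")
    base = np.nanmin(zvals)
    filled = np.where(ok, zvals, base)
    peaks = profile_peaks(filled, prominence_mm)
    peaks = [p for p in peaks if ok[p]]
    if len(peaks) == 0:
        raise ValueError("cusp not found: no peak above prominence")
    out = {}

    def _mm_point(k):
        q = anchor + ts[k] * perp
        return np.array(
            [
                depth.origin[0] + q[0] * depth.cell_size[0],
                depth.origin[1] + q[1] * depth.cell_size[1],
                zvals[k],
            ]
        )

    if fdi == 3:
        k = peaks[int(np.argmax(filled[peaks]))]
        out["tip"] = _mm_point(k)
        out["buccal"] = out["tip"]
    else:
        buccal_k = max(peaks, key=lambda p: ts[p])
        lingual_k = min(peaks, key=lambda p: ts[p])
        out["buccal"] = _mm_point(buccal_k)
        if lingual_k != buccal_k:
            out["lingual"] = _mm_point(lingual_k)
    return out


def arch_widths(tips: dict) -> dict:
    """Inter-canine / inter-premolar / inter-first-molar distances (mm).

    ``tips`` maps (side, fdi) to the buccal cusp tip in mm; a missing side
    leaves that parameter absent.
    """
    names = {3: "inter_canine", 4: "inter_premolar", 6: "inter_molar"}
    out = {}
    for fdi, name in names.items():
        left = tips.get(("left", fdi))
        right = tips.get(("right", fdi))
        if left is not None and right is not None:
            out[name] = float(np.linalg.norm(np.asarray(left) - np.asarray(right)))
    return out
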