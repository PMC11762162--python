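"""Teeth/gum classification of colored scan points with a fixed-radius
nearest-neighbor (FRNN) gravitational classifier.

Every scan point carries an HSV color; candidates are the labeled training
samples within radius R of the query in color space (Euclidean over the
circular hue difference, saturation and value).  Each candidate exerts an
inverse-square "gravitational" pull whose sign encodes its class
(teeth = -1, gum = +1); the query is labeled teeth when the summed force is
negative and gum otherwise — ties, including an empty candidate set, go to
gum.

The classifier is also exposed with a scikit-learn-compatible surface
(:class:`FrnnClassifier`) so it slots into sklearn pipelines and model
selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import ColoredPointCloud, DepthMap

__all__ = [
    "TEETH",
    "GUM",
    "FrnnModel",
    "FrnnClassifier",
    "color_distance",
    "frnn_candidates",
    "gravity_score",
    "classify_point",
    "classify_cloud",
    "teeth_cloud_and_depthmap",
    "default_training_samples",
]

TEETH, GUM = 1, 2
_SIGN = {TEETH: -1.0, GUM: +1.0}


def color_distance(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Euclidean HSV distance with circular hue: d_h = min(|dh|, 1 - |dh|)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    dh = np.abs(a[..., 0] - b[..., 0])
    dh = np.minimum(dh, 1.0 - dh)
    return np.sqrt(dh**2 + (a[..., 1] - b[..., 1]) ** 2 + (a[..., 2] - b[..., 2]) ** 2)


@dataclass
class FrnnModel:
    """Training samples plus the FRNN radius and the distance floor."""

    samples: np.ndarray  # (n, 3) HSV
    labels: np.ndarray  # (n,) in {1 teeth, 2 gum}
    radius: float = 0.15
    eps: float = 1e-6

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.radius <= 0 or self.eps <= 0:
            raise ValueError("radius and eps must be positive")
        if len(self.samples) == 0:
            raise ValueError("training set must be nonempty")
        present = set(np.unique(self.labels))
        if not present <= {TEETH, GUM}:
            raise ValueError("labels must be 1 (teeth) or 2 (gum)")
        if present != {TEETH, GUM}:
            raise ValueError("training set must contain both classes")


def frnn_candidates(model: FrnnModel, s_input) -> np.ndarray:
    """Indices of training samples strictly within the radius of the query."""
    d = color_distance(model.samples, np.asarray(s_input, dtype=float)[None, :])
    return np.nonzero(d < model.radius)[0]


def gravity_score(model: FrnnModel, s_input, candidates=None) -> float:
    """Signed inverse-square force sum; empty candidate set scores 0."""
    if candidates is None:
        candidates = frnn_candidates(model, s_input)
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        return 0.0
    d = color_distance(model.samples[candidates], np.asarray(s_input, dtype=float)[None, :])
    d = np.maximum(d, model.eps)
    signs = np.where(model.labels[candidates] == TEETH, -1.0, 1.0)
    return float(np.sum(signs / d**2))


def classify_point(model: FrnnModel, s_input) -> int:
    """Teeth when the summed force is negative; gum otherwise (tie -> gum)."""
    return TEETH if gravity_score(model, s_input) < 0 else GUM


def classify_cloud(model: FrnnModel, colors: np.ndarray, chunk: int = 4096) -> np.ndarray:
    """Vectorised :func:`classify_point` over many HSV colors."""
    colors = np.asarray(colors, dtype=float)
    out = np.empty(len(colors), dtype=int)
    sam = model.samples
    signs = np.where(model.labels == TEETH, -1.0, 1.0)
    for start in range(0, len(colors), chunk):
        q = colors[start : start + chunk]
        dh = np.abs(q[:, None, 0] - sam[None, :, 0])
        dh = np.minimum(dh, 1.0 - dh)
        d = np.sqrt(
            dh**2 + (q[:, None, 1] - sam[None, :, 1]) ** 2 + (q[:, None, 2] - sam[None, :, 2]) ** 2
        )
        inside = d < model.radius
        F = np.sum(np.where(inside, signs[None, :] / np.maximum(d, model.eps) ** 2, 0.0), axis=1)
        out[start : start + chunk] = np.where(F < 0, TEETH, GUM)
    return out


class FrnnClassifier:
    """scikit-learn-style wrapper around the FRNN gravitational classifier.

    Parameters
    ----------
    radius : float
        FRNN radius in HSV units.
    eps : float
        Distance floor preventing division by zero at exact color matches.
    """

    def __init__(self, radius: float = 0.15, eps: float = 1e-6):
        self.radius = radius
        self.eps = eps

    def get_params(self, deep: bool = True) -> dict:
        return {"radius": self.radius, "eps": self.eps}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in ("radius", "eps"):
                raise ValueError(f"unknown parameter {k}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (n_samples, 3) HSV")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        self.model_ = FrnnModel(X, y, radius=self.radius, eps=self.eps)
        self.classes_ = np.array([TEETH, GUM])
        return self

    def predict(self, X):
        if not hasattr(self, "model_"):
            raise ValueError("FrnnClassifier is not fitted yet; call fit first")
        return classify_cloud(self.model_, np.asarray(X, dtype=float))

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=int)))


def default_training_samples(n_per_class: int = 200, seed: int = 0, jitter: float = 0.03):
    """Labeled HSV samples drawn from the phantom's color model.

    Teeth: near-white enamel (low saturation, high value); gum: pink mucosa.
    For real scans a user-supplied labeled CSV replaces these.
    """
    rng = np.random.default_rng(seed)
    th = np.mod(0.11 + rng.normal(0, jitter / 3.0, n_per_class), 1.0)
    ts = np.clip(0.06 + rng.normal(0, jitter, n_per_class), 0.0, 0.19)
    tv = np.clip(0.95 + rng.normal(0, jitter, n_per_class), 0.0, 1.0)
    gh = np.mod(0.97 + rng.normal(0, jitter / 3.0, n_per_class), 1.0)
    gs = np.clip(0.55 + rng.normal(0, jitter, n_per_class), 0.41, 1.0)
    gv = np.clip(0.80 + rng.normal(0, jitter, n_per_class), 0.0, 1.0)
    X = np.concatenate(
        [np.stack([th, ts, tv], axis=1), np.stack([gh, gs, gv], axis=1)], axis=0
    )
    y = np.concatenate([np.full(n_per_class, TEETH), np.full(n_per_class, GUM)])
    return X, y


def load_training_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a labeled HSV training table (columns h, s, v, label)."""
    import pandas as pd

    df = pd.read_csv(path)
    need = {"h", "s", "v", "label"}
    if not need <= set(df.columns):
        raise ValueError(f"training CSV must have columns {sorted(need)}")
    return df[["h", "s", "v"]].to_numpy(float), df["label"].to_numpy(int)


def teeth_cloud_and_depthmap(
    cloud: ColoredPointCloud,
    model: FrnnModel,
    grid_mm: float = 0.2,
    min_cluster_points: int = 30,
) -> tuple[ColoredPointCloud, DepthMap]:
    """Classify the cloud, keep teeth points, and rasterise their depth map.

    Planar connected clusters of valid cells smaller than
    ``min_cluster_points`` are dropped as specks.  The depth map stores the
    maximum z (mm) per (x, y) grid cell with a validity mask.
    """
    labels = classify_cloud(model, cloud.colors_hsv)
    keep = labels == TEETH
    if not keep.any():
        raise ValueError("no teeth detected")
    pts = cloud.points[keep]
    lo = pts[:, :2].min(axis=0) - grid_mm
    shape = np.ceil((pts[:, :2].max(axis=0) - lo) / grid_mm).astype(int) + 2
    vals = np.full(tuple(shape), -np.inf)
    ij = np.floor((pts[:, :2] - lo) / grid_mm).astype(int)
    for (i, j), z in zip(ij, pts[:, 2]):
        if z > vals[i, j]:
            vals[i, j] = z
    valid = np.isfinite(vals)
    lab, n = ndimage.label(valid)
    if n > 0:
        sizes = ndimage.sum(valid, lab, range(1, n + 1))
        small = np.nonzero(sizes < min_cluster_points)[0] + 1
        if len(small):
            valid &= ~np.isin(lab, small)
    if not valid.any():
        raise ValueError("no teeth detected")
    vals = np.where(valid, vals, 0.0)
    depth = DepthMap(
        vals,
        valid,
        cell_size=(grid_mm, grid_mm),
        origin=(float(lo[0]), float(lo[1])),
        z_units="mm",
        z_scale=1.0,
    )
    teeth = ColoredPointCloud(
        cloud.points[keep],
        cloud.colors_hsv[keep],
        cloud.labels[keep] if cloud.labels is not None else None,
    )
    return teeth, depth
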