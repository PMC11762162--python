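"""Small shared geometry helpers (rotations, arc-length tables)."""

from __future__ import annotations

import numpy as np


def rot_z(deg: float) -> np.ndarray:
    """Rotation about the axial (z) axis — in-plane jaw rotation."""
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def rot_x(deg: float) -> np.ndarray:
    """Rotation about the frontal (x) axis — mandibular inclination."""
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


class ParabolicArch:
    """Arc-length parametrisation of the arch curve ``y = a x**2``.

    Arc coordinates are signed: negative toward the patient-right half
    (x > 0 ... no — by package convention 'left' is the x < 0 half, so
    negative arc runs into x > 0).  ``point(s)`` returns (x, y);
    ``frame(s)`` additionally returns the unit tangent (direction of
    increasing arc) and the outward (buccal) unit normal.
    """

    def __init__(self, a: float, s_max: float, n: int = 4096):
        self.a = float(a)
        x = np.linspace(0.0, 1.5 * s_max, n)
        dy = 2.0 * self.a * x
        ds = np.sqrt(1.0 + dy**2)
        s = np.concatenate(([0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(x))))
        self._s = s
        self._x = x

    def _x_of(self, s_abs: np.ndarray) -> np.ndarray:
        return np.interp(s_abs, self._s, self._x)

    def point(self, s):
        s = np.asarray(s, dtype=float)
        x = np.sign(-s) * self._x_of(np.abs(s))  # left (negative arc) -> x < 0
        return np.stack([x, self.a * x**2], axis=-1)

    def frame(self, s):
        s = np.asarray(s, dtype=float)
        p = self.point(s)
        x = p[..., 0]
        # tangent in direction of increasing arc
        sign = np.where(s >= 0, -1.0, -1.0)  # increasing s decreases x
        tx = sign * np.ones_like(x)
        ty = sign * 2.0 * self.a * x
        norm = np.sqrt(tx**2 + ty**2)
        t = np.stack([tx / norm, ty / norm], axis=-1)
        # outward (buccal) normal: away from the concave (+y interior) side
        n = np.stack([t[..., 1], -t[..., 0]], axis=-1)
        # orient outward: at the apex outward is -y
        flip = n[..., 1] > 0
        n = np.where(flip[..., None], -n, n)
        return p, t, n
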