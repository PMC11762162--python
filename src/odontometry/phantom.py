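"""Synthetic dental phantoms: CBCT-like volumes and colored scan clouds.

The generator builds two dental arches of 12 teeth each (right 1st molar to
left 1st molar) placed tangentially along a parabolic arch curve.  Teeth are
superellipsoids whose mesio-distal extent is the specified width, so ground
truth is analytically controlled.  Default per-type widths are realistic
clinical means (central incisor 7.25 mm ... 1st molar 11.03 mm), the default
voxel spacing is 0.3 mm, and intensities follow a Hounsfield-like ordering:
background 0, soft tissue 300, bone 900, teeth 1600, metal streaks 3000.

Every generated case carries a :class:`PhantomGroundTruth` twin with true
landmark coordinates, widths, cusp tips, voxel labels and the jaw midline so
that each pipeline stage can be validated without clinical data.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np

from ._geometry import ParabolicArch, rot_x, rot_z
from .io import ColoredPointCloud, VoxelVolume

__all__ = [
    "PhantomSpec",
    "ToothTruth",
    "PhantomGroundTruth",
    "generate_cbct_phantom",
    "generate_scan_phantom",
    "DEFAULT_WIDTHS_MM",
]

#: mean mesio-distal widths per FDI position 1..6 (mm)
DEFAULT_WIDTHS_MM = (7.25, 6.74, 7.63, 7.66, 7.36, 11.03)
#: bucco-lingual crown depths per FDI position 1..6 (mm)
DEFAULT_DEPTHS_MM = (7.0, 6.5, 8.0, 9.0, 9.5, 11.0)

INTENSITY = {"background": 0.0, "soft": 300.0, "bone": 900.0, "tooth": 1600.0, "metal": 3000.0}


@dataclass
class PhantomSpec:
    """Parameters of a synthetic two-arch dental case.

    ``arch_coeff`` is the parabola coefficient a in y = a x² (mm⁻¹); the
    default 0.055 yields arch widths in the clinical range (inter-canine
    ≈ 29 mm, inter-first-molar ≈ 52 mm).  ``jaw_gap_mm`` is the inter-occlusal
    gap (0 = closed bite, negative = overlap).  ``alpha_deg`` rotates the whole
    dentition about the frontal axis (mandibular inclination), ``inplane_deg``
    about the axial axis.  ``crowding`` maps a tooth key "jaw-side-fdi"
    (e.g. ``"lower-left-1"``) to (mesio-distal shift mm, bucco-lingual shift
    mm, z-axis rotation deg).
    """

    widths_mm: tuple = DEFAULT_WIDTHS_MM
    depths_mm: tuple = DEFAULT_DEPTHS_MM
    height_mm: float = 8.0
    arch_coeff: float = 0.055
    interdental_gap_mm: float = 0.6
    jaw_gap_mm: float = 4.0
    alpha_deg: float = 0.0
    inplane_deg: float = 0.0
    crowding: dict = field(default_factory=dict)
    missing: tuple = ()
    noise_std: float = 60.0
    metal_streaks: bool = False
    spacing_mm: float = 0.3
    squareness: float = 4.0
    seed: int = 0
    #: centre of the in-plane (head-yaw) rotation, mm in the volume frame.
    #: The default sits ~45 mm posterior of the incisors, at the cranial yaw
    #: axis (condylar/odontoid level): in-plane misalignment in practice is
    #: head rotation, not rotation about the dental arch itself.
    yaw_center_mm: tuple = (36.0, 59.0)
    # scan-specific
    scan_jaw: str = "upper"
    scan_step_mm: float = 0.15
    gum_step_mm: float = 0.25
    color_jitter: float = 0.03
    cusp_height_mm: float = 1.6
    cusp_sigma_mm: float = 1.1

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.widths_mm) or len(self.widths_mm) != 6:
            raise ValueError("widths_mm must be 6 positive values (FDI 1..6)")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if self.scan_jaw not in ("upper", "lower"):
            raise ValueError("scan_jaw must be 'upper' or 'lower'")
        for key in self.crowding:
            jaw, side, fdi = key.split("-")
            if jaw not in ("upper", "lower") or side not in ("left", "right") or int(fdi) not in range(1, 7):
                raise ValueError(f"bad crowding key {key!r}")


@dataclass
class ToothTruth:
    """Ground truth for one tooth: FDI position, landmarks and cusp tips (mm)."""

    tooth_id: int
    jaw: str
    side: str
    fdi: int
    center: np.ndarray
    md_axis: np.ndarray  # unit vector, mesial direction (toward midline)
    mesial: np.ndarray
    distal: np.ndarray
    width: float
    height: float
    depth: float
    cusps: dict = field(default_factory=dict)

    def __post_init__(self):
        assert abs(self.width - float(np.linalg.norm(self.distal - self.mesial))) < 1e-9


@dataclass
class PhantomGroundTruth:
    teeth: list
    alpha_deg: float
    inplane_deg: float
    midline_point: dict  # per jaw: anterior midline point (mm, 2D in (x,y))
    midline_axis: dict  # per jaw: unit (x,y) vector pointing posteriorly
    tooth_labels: np.ndarray | None = None  # per-voxel tooth id (0 = none)
    jaw_labels: np.ndarray | None = None  # 0 background, 1 upper, 2 lower
    arch_widths: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def teeth_of(self, jaw: str) -> list:
        return [t for t in self.teeth if t.jaw == jaw]

    def find(self, jaw: str, side: str, fdi: int) -> ToothTruth:
        for t in self.teeth:
            if t.jaw == jaw and t.side == side and t.fdi == fdi:
                return t
        raise KeyError((jaw, side, fdi))


# ---------------------------------------------------------------------------
# layout

# volume geometry (mm): fixed stage large enough for ±15° in-plane rotation
VOL_SIZE = (72.0, 64.0, 44.0)
ARCH_APEX = np.array([36.0, 14.0])  # (x, y) mm of the arch apex in the volume
ROT_CENTER = np.array([36.0, 32.0, 22.0])  # rotations applied about this point
Z_MID = 22.0  # occlusal mid-plane


def _layout(spec: PhantomSpec):
    """Per-tooth arc positions and sizes. Returns list of dicts."""
    arch = ParabolicArch(spec.arch_coeff, s_max=80.0)
    out = []
    for side, sgn in (("left", 1.0), ("right", -1.0)):
        s = spec.interdental_gap_mm / 2.0
        for fdi in range(1, 7):
            w = spec.widths_mm[fdi - 1]
            center_arc = s + w / 2.0
            s += w + spec.interdental_gap_mm
            for jaw in ("upper", "lower"):
                if f"{jaw}-{side}-{fdi}" in spec.missing or (jaw, side, fdi) in spec.missing:
                    continue
                out.append(
                    dict(
                        jaw=jaw,
                        side=side,
                        fdi=fdi,
                        arc=sgn * center_arc,
                        width=w,
                        depth=spec.depths_mm[fdi - 1],
                        height=spec.height_mm,
                    )
                )
    return arch, out


def _make_transform(spec: PhantomSpec, for_scan: bool):
    """Rigid placement transform: head yaw (in-plane) then inclination.

    Returns (T, Rdir): T maps (N, 3) arch-frame points to the volume frame;
    Rdir rotates direction vectors.  The yaw is applied about the cranial yaw
    axis (posterior of the arch), the inclination about the arch band centre.
    A scan phantom lies flat on the scanner bed, so only the in-plane
    rotation applies, about the model (band) centroid.
    """
    Rz = rot_z(spec.inplane_deg)
    if for_scan:
        yc = np.array([0.0, 18.0, 0.0])

        def T(p):
            return yc + (Rz @ (np.atleast_2d(p) - yc).T).T

        return T, Rz
    Rx = rot_x(spec.alpha_deg)
    yc = np.array([spec.yaw_center_mm[0], spec.yaw_center_mm[1], Z_MID])
    rc = ROT_CENTER

    def T(p):
        p1 = yc + (Rz @ (np.atleast_2d(p) - yc).T).T
        return rc + (Rx @ (p1 - rc).T).T

    return T, Rx @ Rz


def _tooth_frames(spec: PhantomSpec, for_scan: bool = False):
    """3D center + orthonormal local frame per tooth, rotations applied.

    Local frame columns: mesio-distal axis (mesial direction), buccal outward
    normal, occlusal-up z.  For CBCT the two jaws sit either side of the
    occlusal mid-plane; for a scan phantom the selected jaw is laid out
    crown-up with the gum base at z = 0.
    """
    arch, layout = _layout(spec)
    T, R = _make_transform(spec, for_scan)
    teeth = []
    for rec in layout:
        p2, t2, n2 = arch.frame(rec["arc"])
        # mesial = toward midline = direction of decreasing |arc|
        m2 = -t2 if rec["arc"] >= 0 else t2
        m3 = np.array([m2[0], m2[1], 0.0])
        b3 = np.array([n2[0], n2[1], 0.0])
        z3 = np.array([0.0, 0.0, 1.0])
        key = f"{rec['jaw']}-{rec['side']}-{rec['fdi']}"
        dmd, dbl, rz = spec.crowding.get(key, (0.0, 0.0, 0.0))
        if rz:
            Rz = rot_z(rz)
            m3, b3 = Rz @ m3, Rz @ b3
        if for_scan:
            cz = rec["height"] / 2.0  # gum base at z=0, crown up
            zsign = 1.0
        else:
            half_gap = spec.jaw_gap_mm / 2.0
            if rec["jaw"] == "upper":
                cz = Z_MID + half_gap + rec["height"] / 2.0
                zsign = -1.0  # occlusal surface faces down
            else:
                cz = Z_MID - half_gap - rec["height"] / 2.0
                zsign = 1.0
        cx, cy = ARCH_APEX + p2 if not for_scan else p2
        center = np.array([cx, cy, cz]) + dmd * m3 + dbl * b3
        center = T(center)[0]
        m3, b3, z3 = R @ m3, R @ b3, R @ z3
        teeth.append(
            dict(rec, center=center, m=m3, b=b3, z=z3, zsign=zsign, key=key)
        )
    return arch, teeth, (T, R)


def _truth_from_frames(spec, teeth, TR, for_scan: bool):
    T, R = TR
    truths = []
    for i, t in enumerate(teeth, start=1):
        mes = t["center"] + (t["width"] / 2.0) * t["m"]
        dist = t["center"] - (t["width"] / 2.0) * t["m"]
        truths.append(
            ToothTruth(
                tooth_id=i,
                jaw=t["jaw"],
                side=t["side"],
                fdi=t["fdi"],
                center=t["center"],
                md_axis=t["m"],
                mesial=mes,
                distal=dist,
                width=t["width"],
                height=t["height"],
                depth=t["depth"],
            )
        )
    # the true midline point sits on the outer (buccal) jaw boundary at the
    # arch apex — the same locus the profile-based estimator traces
    buccal = spec.depths_mm[0] / 2.0
    if for_scan:
        apex3 = np.array([0.0, -buccal, 0.0])
    else:
        apex3 = np.array([ARCH_APEX[0], ARCH_APEX[1] - buccal, Z_MID])
    apex_rot = T(apex3)[0]
    axis_rot = R @ np.array([0.0, 1.0, 0.0])
    a2 = axis_rot[:2] / np.linalg.norm(axis_rot[:2])
    midpt = {j: apex_rot[:2].copy() for j in ("upper", "lower")}
    midax = {j: a2.copy() for j in ("upper", "lower")}
    return truths, midpt, midax


# ---------------------------------------------------------------------------
# CBCT rendering


def _render_superellipsoid(grid_shape, spacing, center, axes, radii, p):
    """Voxel mask of a superellipsoid on a bounding sub-grid.

    Returns (slices, mask) where mask is the inside test evaluated at voxel
    centers of the sub-grid.
    """
    r = float(np.max(radii)) * np.sqrt(3.0) + 2.0 * spacing
    lo = np.maximum(np.floor((center - r) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center + r) / spacing).astype(int) + 1, grid_shape)
    if np.any(lo >= hi):
        return None, None
    ix = np.arange(lo[0], hi[0]) * spacing
    iy = np.arange(lo[1], hi[1]) * spacing
    iz = np.arange(lo[2], hi[2]) * spacing
    X, Y, Z = np.meshgrid(ix, iy, iz, indexing="ij")
    d = np.stack([X - center[0], Y - center[1], Z - center[2]], axis=-1)
    q = d @ axes  # local coordinates (axes columns orthonormal)
    val = np.zeros(q.shape[:3])
    for k in range(3):
        val += np.abs(q[..., k] / radii[k]) ** p
    mask = val <= 1.0
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return sl, mask


def generate_cbct_phantom(spec: PhantomSpec):
    """Render the CBCT-like volume plus its ground truth.

    Deterministic for a fixed seed.  Tooth overlap caused by crowding is
    recorded as a warning in the truth (stress cases are intentional).
    """
    rng = np.random.default_rng(spec.seed)
    spacing = spec.spacing_mm
    shape = tuple(int(round(s / spacing)) for s in VOL_SIZE)
    vol = np.zeros(shape, dtype=np.float32)
    tooth_labels = np.zeros(shape, dtype=np.uint8)

    arch, teeth, TR = _tooth_frames(spec, for_scan=False)
    truths, midpt, midax = _truth_from_frames(spec, teeth, TR, for_scan=False)
    truth = PhantomGroundTruth(
        teeth=truths,
        alpha_deg=spec.alpha_deg,
        inplane_deg=spec.inplane_deg,
        midline_point=midpt,
        midline_axis=midax,
    )

    # soft-tissue ellipse (all z), evaluated in the yaw-rotated frame
    xs = (np.arange(shape[0]) + 0.0) * spacing
    ys = (np.arange(shape[1]) + 0.0) * spacing
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    th = np.deg2rad(spec.inplane_deg)
    yx, yy = spec.yaw_center_mm
    u = np.cos(th) * (X - yx) + np.sin(th) * (Y - yy)
    v = -np.sin(th) * (X - yx) + np.cos(th) * (Y - yy)
    ecx, ecy = ROT_CENTER[0] - yx, ARCH_APEX[1] + 18.0 - yy
    soft2d = ((u - ecx) / 34.0) ** 2 + ((v - ecy) / 30.0) ** 2 <= 1.0
    vol[soft2d, :] = INTENSITY["soft"]

    # bone root blocks behind the crowns
    for t in teeth:
        root_h = 6.0
        root_center = t["center"] - t["zsign"] * t["z"] * (t["height"] / 2.0 + root_h / 2.0)
        axes = np.stack([t["m"], t["b"], t["z"]], axis=1)
        sl, mask = _render_superellipsoid(
            shape, spacing, root_center, axes,
            np.array([t["width"] / 2.0 + 0.6, t["depth"] / 2.0 + 0.6, root_h / 2.0]),
            spec.squareness,
        )
        if sl is not None:
            vol[sl][mask] = INTENSITY["bone"]

    overlap_px = 0
    for i, t in enumerate(teeth, start=1):
        axes = np.stack([t["m"], t["b"], t["z"]], axis=1)
        sl, mask = _render_superellipsoid(
            shape, spacing, t["center"], axes,
            np.array([t["width"] / 2.0, t["depth"] / 2.0, t["height"] / 2.0]),
            spec.squareness,
        )
        if sl is None:
            continue
        prev = tooth_labels[sl][mask]
        overlap_px += int(np.count_nonzero(prev))
        tooth_labels[sl][mask] = i
        vol[sl][mask] = INTENSITY["tooth"]
    if overlap_px:
        truth.warnings.append(f"crowding produced {overlap_px} overlapping tooth voxels")

    if spec.metal_streaks:
        molars = [t for t in teeth if t["fdi"] == 6]
        target = molars[int(rng.integers(len(molars)))]
        c = target["center"] / spacing
        zc = int(round(c[2]))
        for ang in np.linspace(0.0, np.pi, 8, endpoint=False) + float(rng.uniform(0, np.pi / 8)):
            d = np.array([np.cos(ang), np.sin(ang)])
            rr = np.arange(-25.0, 25.0, spacing / 2.0) / spacing
            px = np.round(c[0] + rr * d[0]).astype(int)
            py = np.round(c[1] + rr * d[1]).astype(int)
            ok = (px >= 0) & (px < shape[0]) & (py >= 0) & (py < shape[1])
            for dz in (-1, 0, 1):
                z = zc + dz
                if 0 <= z < shape[2]:
                    vol[px[ok], py[ok], z] = INTENSITY["metal"]

    if spec.noise_std > 0:
        vol += rng.normal(0.0, spec.noise_std, size=shape).astype(np.float32)

    jaw_labels = np.zeros(shape, dtype=np.uint8)
    upper_ids = [tt.tooth_id for tt in truths if tt.jaw == "upper"]
    jaw_labels[np.isin(tooth_labels, upper_ids)] = 1
    jaw_labels[(tooth_labels > 0) & (jaw_labels == 0)] = 2
    truth.tooth_labels = tooth_labels
    truth.jaw_labels = jaw_labels

    volume = VoxelVolume(vol, spacing=(spacing, spacing, spacing))
    return volume, truth


# ---------------------------------------------------------------------------
# scan rendering


def _cusp_layout(t: dict, spec: PhantomSpec):
    """Cusp bump positions (u, v) in local tooth coordinates, u toward mesial."""
    a = t["width"] / 2.0
    b = t["depth"] / 2.0
    amp, amp_l = spec.cusp_height_mm, spec.cusp_height_mm * 0.8
    if t["fdi"] == 3:
        return {"tip": (0.0, 0.0, amp)}
    if t["fdi"] in (4, 5):
        return {"buccal": (0.0, 0.45 * b, amp), "lingual": (0.0, -0.45 * b, amp_l)}
    if t["fdi"] == 6:
        return {
            "mesiobuccal": (0.5 * a, 0.45 * b, amp),
            "mesiolingual": (0.5 * a, -0.45 * b, amp_l),
            "distobuccal": (-0.5 * a, 0.45 * b, amp_l),
            "distolingual": (-0.5 * a, -0.45 * b, amp_l * 0.9),
        }
    return {}


def _crown_height(u, v, a, b, h, p):
    base = 1.0 - np.abs(u / a) ** p - np.abs(v / b) ** p
    return h * np.clip(base, 0.0, None) ** (1.0 / p)


def generate_scan_phantom(spec: PhantomSpec):
    """Sample a colored occlusal-surface point cloud of one jaw with truth.

    Tooth points are near-white (low saturation, high value), gum points pink;
    cusps are smooth Gaussian bumps whose apices are included as explicit
    sample points so the true cusp tip is the arg-max of z over the tooth's
    points.  The plaster model lies flat, so only the in-plane rotation of the
    spec applies.
    """
    rng = np.random.default_rng(spec.seed + 1)
    jaw = spec.scan_jaw
    arch, teeth, TR = _tooth_frames(spec, for_scan=True)
    teeth = [t for t in teeth if t["jaw"] == jaw]
    truths_all, midpt, midax = _truth_from_frames(spec, teeth, TR, for_scan=True)
    T, R = TR
    p = spec.squareness

    pts, cols, labs = [], [], []
    for tt, t in zip(truths_all, teeth):
        a, b, h = t["width"] / 2.0, t["depth"] / 2.0, t["height"]
        uu = np.arange(-a, a + 1e-9, spec.scan_step_mm)
        vv = np.arange(-b, b + 1e-9, spec.scan_step_mm)
        U, V = np.meshgrid(uu, vv, indexing="ij")
        inside = np.abs(U / a) ** p + np.abs(V / b) ** p < 1.0
        U, V = U[inside], V[inside]
        Z = _crown_height(U, V, a, b, h, p)
        cusps = _cusp_layout(t, spec)
        for name, (cu, cv, amp) in cusps.items():
            Z = Z + amp * np.exp(-((U - cu) ** 2 + (V - cv) ** 2) / (2.0 * spec.cusp_sigma_mm**2))
        # explicit apex samples so truth == arg-max over samples
        for name, (cu, cv, amp) in cusps.items():
            za = _crown_height(np.array([cu]), np.array([cv]), a, b, h, p)[0]
            for oname, (ou, ov, oamp) in cusps.items():
                za += oamp * np.exp(-((cu - ou) ** 2 + (cv - ov) ** 2) / (2.0 * spec.cusp_sigma_mm**2))
            U = np.concatenate([U, [cu]])
            V = np.concatenate([V, [cv]])
            Z = np.concatenate([Z, [za]])
        world = (
            t["center"][None, :]
            - np.array([0, 0, t["height"] / 2.0])[None, :]
            + U[:, None] * t["m"][None, :]
            + V[:, None] * t["b"][None, :]
            + Z[:, None] * np.array([0.0, 0.0, 1.0])[None, :]
        )
        n = world.shape[0]
        h_col = np.mod(0.11 + rng.normal(0, spec.color_jitter / 3.0, n), 1.0)
        s_col = np.clip(0.06 + rng.normal(0, spec.color_jitter, n), 0.0, 0.19)
        v_col = np.clip(0.95 + rng.normal(0, spec.color_jitter, n), 0.0, 1.0)
        pts.append(world)
        cols.append(np.stack([h_col, s_col, v_col], axis=1))
        labs.append(np.full(n, tt.tooth_id))
        # record cusp truths (world coordinates)
        cusp_world = {}
        for name, (cu, cv, amp) in cusps.items():
            za = _crown_height(np.array([cu]), np.array([cv]), a, b, h, p)[0]
            for oname, (ou, ov, oamp) in cusps.items():
                za += oamp * np.exp(-((cu - ou) ** 2 + (cv - ov) ** 2) / (2.0 * spec.cusp_sigma_mm**2))
            cusp_world[name] = (
                t["center"]
                - np.array([0, 0, t["height"] / 2.0])
                + cu * t["m"]
                + cv * t["b"]
                + za * np.array([0.0, 0.0, 1.0])
            )
        tt.cusps = cusp_world

    # gum band along the arch (below the crowns)
    s_end = max(abs(t["arc"]) for t in teeth) + spec.widths_mm[5] / 2.0 + 2.0
    ss = np.arange(-s_end, s_end, spec.gum_step_mm)
    vv = np.arange(-7.0, 7.0, spec.gum_step_mm)
    S, VV = np.meshgrid(ss, vv, indexing="ij")
    p2, t2, n2 = arch.frame(S.ravel())
    base = p2 + VV.ravel()[:, None] * n2
    zg = 0.4 * (1.0 - (VV.ravel() / 7.0) ** 2)
    world = T(np.stack([base[:, 0], base[:, 1], zg], axis=1))
    n = world.shape[0]
    h_col = np.mod(0.97 + rng.normal(0, spec.color_jitter / 3.0, n), 1.0)
    s_col = np.clip(0.55 + rng.normal(0, spec.color_jitter, n), 0.41, 1.0)
    v_col = np.clip(0.80 + rng.normal(0, spec.color_jitter, n), 0.0, 1.0)
    pts.append(world)
    cols.append(np.stack([h_col, s_col, v_col], axis=1))
    labs.append(np.zeros(n, dtype=int))

    cloud = ColoredPointCloud(np.vstack(pts), np.vstack(cols), np.concatenate(labs))
    truth = PhantomGroundTruth(
        teeth=truths_all,
        alpha_deg=0.0,
        inplane_deg=spec.inplane_deg,
        midline_point={jaw: midpt[jaw]},
        midline_axis={jaw: midax[jaw]},
    )
    # true arch widths from cusp tips
    def _tip(side, fdi, name):
        try:
            return truth.find(jaw, side, fdi).cusps[name]
        except KeyError:
            return None

    pairs = {
        "inter_canine": ("tip", 3),
        "inter_premolar": ("buccal", 4),
        "inter_molar": ("mesiobuccal", 6),
    }
    for key, (name, fdi) in pairs.items():
        lt, rt = _tip("left", fdi, name), _tip("right", fdi, name)
        if lt is not None and rt is not None:
            truth.arch_widths[key] = float(np.linalg.norm(lt - rt))
    return cloud, truth
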