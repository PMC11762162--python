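"""Reading, writing and in-memory containers for volumes, colored scans and depth maps.

Axis semantics are fixed throughout the package: array index order is
``(x, y, z)`` with x the frontal (left-right) axis, y the sagittal
(anterior-posterior) axis and z the axial (inferior-superior) axis.  All
indexing is zero-based half-open; distances in millimetres always honour the
per-axis voxel spacing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "VoxelVolume",
    "RegionOfInterest",
    "ColoredPointCloud",
    "DepthMap",
    "load_volume",
    "save_volume",
    "load_colored_mesh",
    "save_colored_cloud",
    "crop",
    "rgb_to_hsv",
    "hsv_to_rgb",
]


@dataclass
class VoxelVolume:
    """A 3D scalar grid with Hounsfield-like intensities.

    Parameters
    ----------
    intensities : ndarray of shape (Nx, Ny, Nz)
        Scalar grid; must be finite.
    spacing : tuple of float
        Millimetres per voxel along (x, y, z); strictly positive.
    origin : tuple of float
        Millimetre offset of voxel (0, 0, 0).
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = (0.3, 0.3, 0.3)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D array")
        if min(self.intensities.shape) < 1:
            raise ValueError("all three dimensions must be >= 1")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensity grid contains NaN/Inf")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def voxel_to_mm(self, idx) -> np.ndarray:
        """Millimetre coordinate of a (possibly fractional) voxel index."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)


@dataclass
class RegionOfInterest:
    """Per-axis zero-based half-open integer bounds ``[low, high)``."""

    low: tuple[int, int, int]
    high: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.low = tuple(int(v) for v in self.low)
        self.high = tuple(int(v) for v in self.high)
        if any(lo >= hi for lo, hi in zip(self.low, self.high)):
            raise ValueError(f"ROI low must be < high per axis: {self.low} vs {self.high}")


@dataclass
class ColoredPointCloud:
    """Points in millimetres with per-point HSV colors.

    Hue lives on [0, 1) with circular distance; saturation and value on [0, 1].
    ``labels`` is an optional per-point integer label (phantom ground truth or
    classifier output).
    """

    points: np.ndarray
    colors_hsv: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.colors_hsv = np.asarray(self.colors_hsv, dtype=float)
        if self.points.shape[0] != self.colors_hsv.shape[0]:
            raise ValueError("points and colors must have the same length")
        if self.colors_hsv.size:
            h, s, v = self.colors_hsv.T
            if np.any((h < 0) | (h >= 1.0)) or np.any((s < 0) | (s > 1)) or np.any((v < 0) | (v > 1)):
                raise ValueError("HSV channels out of range (h in [0,1), s,v in [0,1])")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.points.shape[0]:
                raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class DepthMap:
    """2D grid of axial surface coordinates paired with a validity mask.

    ``values`` holds the axial coordinate (in ``z_units``) of the occlusal
    surface per (x, y) cell; ``valid`` marks cells covered by the surface.
    ``cell_size``/``origin`` map grid indices to in-plane millimetres and
    ``z_scale`` converts a stored value to millimetres.
    """

    values: np.ndarray
    valid: np.ndarray
    cell_size: tuple[float, float] = (0.3, 0.3)
    origin: tuple[float, float] = (0.0, 0.0)
    z_units: str = "voxel"
    z_scale: float = 0.3

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.shape != self.valid.shape:
            raise ValueError("values and validity mask must share a shape")
        if self.valid.any() and not np.all(np.isfinite(self.values[self.valid])):
            raise ValueError("depth values must be finite wherever valid")
        if self.z_units not in ("voxel", "mm"):
            raise ValueError("z_units must be 'voxel' or 'mm'")

    def z_mm(self) -> np.ndarray:
        return self.values * self.z_scale


# ---------------------------------------------------------------------------
# color space


def rgb_to_hsv(rgb: np.ndarray) -> np.ndarray:
    """Vectorised RGB → HSV, unit ranges, hue on [0, 1)."""
    from matplotlib.colors import rgb_to_hsv as _mpl

    hsv = _mpl(np.clip(np.asarray(rgb, dtype=float), 0.0, 1.0))
    hsv[..., 0] = np.mod(hsv[..., 0], 1.0)
    return hsv


def hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    from matplotlib.colors import hsv_to_rgb as _mpl

    return _mpl(np.asarray(hsv, dtype=float))


# ---------------------------------------------------------------------------
# volumes


def load_volume(path: str | Path) -> VoxelVolume:
    """Load an NRRD or NIfTI-1 volume into the package axis convention.

    Raises a ``ValueError`` naming the offending metadata field when spacing
    is non-positive or the format cannot be identified.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    name = path.name.lower()
    if name.endswith(".nrrd"):
        import SimpleITK as sitk

        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as e:
            raise ValueError(f"{path}: unreadable volume metadata: {e}") from e
        # SimpleITK arrays come back (z, y, x); transpose into (x, y, z).
        arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
        spacing = tuple(img.GetSpacing())
        origin = tuple(img.GetOrigin())
    elif name.endswith(".nii") or name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asarray(img.dataobj)
        if arr.ndim != 3:
            raise ValueError(f"{path}: expected a 3D NIfTI volume, got ndim={arr.ndim}")
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        origin = tuple(float(v) for v in img.affine[:3, 3])
    else:
        raise ValueError(f"{path}: unrecognised volume format (need .nrrd, .nii or .nii.gz)")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"{path}: non-positive voxel spacing in header: {spacing}")
    arr = np.asarray(arr, dtype=np.float32)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: intensity data contains NaN/Inf")
    return VoxelVolume(arr, spacing=spacing, origin=origin)


def save_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume as NRRD or NIfTI-1 (chosen by extension)."""
    path = Path(path)
    name = path.name.lower()
    if name.endswith(".nrrd"):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.intensities.transpose(2, 1, 0)))
        img.SetSpacing(volume.spacing)
        img.SetOrigin(volume.origin)
        sitk.WriteImage(img, str(path))
    elif name.endswith(".nii") or name.endswith(".nii.gz"):
        import nibabel as nib

        affine = np.diag(list(volume.spacing) + [1.0])
        affine[:3, 3] = volume.origin
        nib.save(nib.Nifti1Image(np.asarray(volume.intensities), affine), str(path))
    else:
        raise ValueError(f"{path}: unrecognised volume format")


def crop(volume: VoxelVolume, roi: RegionOfInterest) -> VoxelVolume:
    """Crop to a region of interest; the origin shifts by ``low * spacing``."""
    for ax in range(3):
        if roi.low[ax] < 0 or roi.high[ax] > volume.shape[ax]:
            raise ValueError(
                f"ROI axis {ax} [{roi.low[ax]}, {roi.high[ax]}) outside grid of size {volume.shape[ax]}"
            )
    sl = tuple(slice(lo, hi) for lo, hi in zip(roi.low, roi.high))
    origin = tuple(o + lo * s for o, lo, s in zip(volume.origin, roi.low, volume.spacing))
    return VoxelVolume(volume.intensities[sl].copy(), spacing=volume.spacing, origin=origin)


# ---------------------------------------------------------------------------
# colored meshes / point clouds


def load_colored_mesh(path: str | Path) -> ColoredPointCloud:
    """Load a PLY mesh or point cloud with per-vertex 8-bit RGB into HSV."""
    import trimesh

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    obj = trimesh.load(str(path), process=False)
    if isinstance(obj, trimesh.points.PointCloud):
        points = np.asarray(obj.vertices, dtype=float)
        colors = obj.colors
    else:
        points = np.asarray(obj.vertices, dtype=float)
        colors = getattr(obj.visual, "vertex_colors", None)
    if colors is None or len(colors) != len(points):
        raise ValueError(
            f"{path}: missing per-vertex color; the PLY must carry uchar red/green/blue "
            "properties on every vertex"
        )
    rgb = np.asarray(colors, dtype=float)[:, :3] / 255.0
    return ColoredPointCloud(points, rgb_to_hsv(rgb))


def save_colored_cloud(cloud: ColoredPointCloud, path: str | Path) -> None:
    """Write a point cloud as ASCII PLY with per-vertex uchar RGB."""
    rgb = np.clip(np.round(hsv_to_rgb(cloud.colors_hsv) * 255.0), 0, 255).astype(np.uint8)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(cloud)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write("end_header\n")
        for p, c in zip(cloud.points, rgb):
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {c[0]} {c[1]} {c[2]}\n")


def save_depthmap(depth: DepthMap, png_path: str | Path, meta_path: str | Path | None = None) -> None:
    """Export a depth map as 16-bit PNG plus JSON scale metadata."""
    import imageio.v3 as iio

    vals = np.where(depth.valid, depth.values, 0.0)
    vmax = float(vals.max()) if vals.size else 1.0
    scale = 65535.0 / vmax if vmax > 0 else 1.0
    iio.imwrite(str(png_path), np.round(vals * scale).astype(np.uint16))
    if meta_path is not None:
        meta = {
            "png_value_scale": scale,
            "cell_size_mm": list(depth.cell_size),
            "origin_mm": list(depth.origin),
            "z_units": depth.z_units,
            "z_scale_mm": depth.z_scale,
        }
        Path(meta_path).write_text(json.dumps(meta, indent=2))
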