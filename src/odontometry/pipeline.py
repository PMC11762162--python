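"""End-to-end orchestration for CBCT volumes and colored model scans.

``run_cbct``: crop → arch curve → panoramic → sagittal slice segmentation →
jaw separation → per-jaw alignment → MIP → tooth identification → landmark
detection → 3D lifting → mesio-distal widths.

``run_scan``: FRNN teeth/gum segmentation → occlusal depth map → tooth
identification on the depth map → landmarks → widths → cusp tips → arch
widths.

Per-tooth failures degrade to flags on the report rather than aborting the
run; stage-level hard errors propagate with the stage name attached.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from . import jaws as J
from . import keypoints as K
from . import panorama as P
from . import scan as S
from .identify import (
    align_jaw,
    compute_mip,
    detect_teeth_on_mip,
    estimate_inclination,
    estimate_midline,
    extract_jaw_profile,
    fixed_midline,
    identification_from_depthmap,
    surface_depth_map,
)
from .io import ColoredPointCloud, RegionOfInterest, VoxelVolume, crop

__all__ = ["PipelineConfig", "ToothMeasurement", "MeasurementReport", "run_cbct", "run_scan"]

_ALLOWED_KEYS = {
    "kind",
    "roi",
    "alpha_deg",
    "panoramic_half_width_vox",
    "frnn_radius",
    "training_samples",
    "delta_d_vox",
    "cascade_stages",
    "cascade_shrink",
    "peak_prominence_mm",
    "min_tooth_spacing_mm",
    "scan_grid_mm",
    "midline_mode",
    "seed",
}


@dataclass
class PipelineConfig:
    """Validated end-to-end configuration.

    ``alpha_deg`` may be a number or ``"estimate"`` to use the principal-
    plane fallback.  ``midline_mode`` is ``"adaptive"`` (default) or
    ``"fixed"`` (scanner-frame baseline).
    """

    kind: str = "cbct"
    roi: tuple | None = None
    alpha_deg: float | str = 0.0
    panoramic_half_width_vox: float = 15.0
    frnn_radius: float = 0.15
    training_samples: str | None = None
    delta_d_vox: float = 8.0
    cascade_stages: int = 1
    cascade_shrink: float = 0.6
    peak_prominence_mm: float = 0.5
    min_tooth_spacing_mm: float = 5.0
    scan_grid_mm: float = 0.2
    midline_mode: str = "adaptive"
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("cbct", "scan"):
            raise ValueError("kind must be 'cbct' or 'scan'")
        if self.panoramic_half_width_vox < 1:
            raise ValueError("panoramic half-width must be >= 1 voxel")
        if not (0 < self.frnn_radius <= 2.0):
            raise ValueError("frnn_radius out of range")
        if self.cascade_stages < 1 or not (0 < self.cascade_shrink <= 1):
            raise ValueError("bad cascade configuration")
        if self.midline_mode not in ("adaptive", "fixed"):
            raise ValueError("midline_mode must be 'adaptive' or 'fixed'")
        if isinstance(self.alpha_deg, str) and self.alpha_deg != "estimate":
            raise ValueError("alpha_deg must be a number or 'estimate'")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _ALLOWED_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class ToothMeasurement:
    jaw: str
    side: str | None
    fdi: int | None
    center_mm: list
    mesial_mm: list | None
    distal_mm: list | None
    width_mm: float | None
    flags: list = field(default_factory=list)


@dataclass
class MeasurementReport:
    kind: str
    teeth: list
    arch_widths_mm: dict = field(default_factory=dict)
    unassigned_slice_masks: int = 0
    flags: list = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def widths_by_tooth(self) -> dict:
        return {
            (t.jaw, t.side, t.fdi): t.width_mm
            for t in self.teeth
            if t.fdi is not None and t.width_mm is not None
        }


def _stage(name):
    """Decorator-ish context: re-raise hard errors with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise type(exc)(f"[{name}] {exc}") from exc
            return False

    return _Ctx()


def _measure_jaw(
    mip, profile, detections, depth, config: PipelineConfig, cell_mm: float, report: MeasurementReport
):
    edge = 0.5 if config.kind == "cbct" else 0.0
    cascade = K.CascadeDetector(
        [K.ReferenceStage(edge_offset=edge)] * config.cascade_stages, config.cascade_shrink
    )
    axes = K.tooth_axes(detections)
    origin = np.asarray(depth.origin, dtype=float)
    tips: dict = {}
    for det in detections:
        rec = ToothMeasurement(
            jaw=det.jaw,
            side=det.side,
            fdi=det.fdi,
            center_mm=list(origin + np.asarray(det.center) * cell_mm),
            mesial_mm=None,
            distal_mm=None,
            width_mm=None,
            flags=list(det.flags),
        )
        report.teeth.append(rec)
        if det.fdi is None:
            continue
        try:
            ax, ms = axes.get(id(det), (None, None))
            roi = K.crop_tooth_roi(mip.values, det, profile, cell_mm=cell_mm, axis=ax, mesial_sign=ms)
            pair = K.run_cascade(cascade, roi)
            rec.flags.extend(pair.flags)
            K.lift_pair(pair, depth)
            rec.mesial_mm = list(pair.mesial_3d)
            rec.distal_mm = list(pair.distal_3d)
            rec.width_mm = K.mesiodistal_width(pair)
            if not (2.0 < rec.width_mm < 16.0):
                rec.flags.append(f"implausible width {rec.width_mm:.2f} mm")
        except Exception as e:  # per-tooth degradation
            rec.flags.append(f"measurement failed: {e}")
            continue
        if config.kind == "scan" and det.fdi in (3, 4, 6) and det.side is not None:
            try:
                cusps = K.cusp_tips(
                    roi, depth, pair, profile, det.fdi, prominence_mm=config.peak_prominence_mm
                )
                tips[(det.side, det.fdi)] = cusps["buccal"] if det.fdi != 3 else cusps["tip"]
            except Exception as e:
                rec.flags.append(f"cusp detection failed: {e}")
    return tips


def run_cbct(volume: VoxelVolume, config: PipelineConfig | None = None) -> MeasurementReport:
    """Measure mesio-distal widths of both jaws from a CBCT-like volume."""
    config = config or PipelineConfig(kind="cbct")
    report = MeasurementReport(kind="cbct", teeth=[], config={**config.__dict__})
    if config.roi is not None:
        lo, hi = config.roi
        with _stage("crop"):
            volume = crop(volume, RegionOfInterest(lo, hi))
    with _stage("arch curve"):
        proj = P.mean_axial_projection(volume)
        curve = P.fit_arch_curve(proj)
    with _stage("panoramic"):
        pano = P.extract_panoramic(volume, curve, w=config.panoramic_half_width_vox)
    with _stage("slice segmentation"):
        thr = J.bright_tail_otsu(volume.intensities)
        slice_masks = J.slice_masks_of_volume(volume, threshold=thr)
    with _stage("jaw separation"):
        # the panoramic averages along arch normals, diluting thin teeth:
        # its segmentation threshold comes from its own intensity histogram
        pano_masks = J.split_panoramic_masks(pano, threshold=J.bright_tail_otsu(pano.values))
        assignment = J.assign_jaws(
            slice_masks, pano_masks, curve, config.panoramic_half_width_vox, volume.shape
        )
        report.unassigned_slice_masks = assignment.unassigned
    cell = volume.spacing[0]
    for jaw, mask in (("upper", assignment.upper), ("lower", assignment.lower)):
        with _stage(f"{jaw} identification"):
            masked = np.where(mask, volume.intensities, 0.0).astype(np.float32)
            jaw_vol = VoxelVolume(masked, volume.spacing, volume.origin)
            if config.alpha_deg == "estimate":
                alpha = estimate_inclination(mask, volume.spacing)
            else:
                alpha = float(config.alpha_deg)
            if alpha != 0.0:
                jaw_vol = align_jaw(jaw_vol, alpha)
                mask_al = align_jaw(
                    VoxelVolume(mask.astype(np.float32), volume.spacing), alpha
                ).intensities > 0.5
            else:
                mask_al = mask
            mip = compute_mip(jaw_vol, jaw=jaw)
            dets = detect_teeth_on_mip(
                mip, threshold=thr / 2.0, min_spacing_mm=config.min_tooth_spacing_mm
            )
            profile = extract_jaw_profile(mip, threshold=thr / 2.0)
            if config.midline_mode == "adaptive":
                profile = estimate_midline(profile, delta_d=config.delta_d_vox)
            else:
                profile = fixed_midline(profile, center_x=volume.shape[0] / 2.0)
            from .identify import assign_fdi

            dets = assign_fdi(dets, profile)
        with _stage(f"{jaw} measurement"):
            depth = surface_depth_map(mask_al, volume, jaw)
            _measure_jaw(mip, profile, dets, depth, config, cell, report)
    return report


def run_scan(cloud: ColoredPointCloud, config: PipelineConfig | None = None, jaw: str = "upper") -> MeasurementReport:
    """Measure widths, cusp tips and arch widths from a colored model scan."""
    config = config or PipelineConfig(kind="scan")
    if config.kind != "scan":
        config = PipelineConfig(**{**config.__dict__, "kind": "scan"})
    report = MeasurementReport(kind="scan", teeth=[], config={**config.__dict__})
    with _stage("teeth segmentation"):
        if config.training_samples:
            X, y = S.load_training_csv(config.training_samples)
        else:
            X, y = S.default_training_samples(seed=config.seed)
        model = S.FrnnModel(X, y, radius=config.frnn_radius)
        teeth_cloud, depth = S.teeth_cloud_and_depthmap(cloud, model, grid_mm=config.scan_grid_mm)
    with _stage("identification"):
        dets, profile, mip = identification_from_depthmap(
            depth,
            jaw=jaw,
            min_spacing_mm=config.min_tooth_spacing_mm,
            delta_d_mm=config.delta_d_vox * 0.3,
            adaptive=config.midline_mode == "adaptive",
        )
    with _stage("measurement"):
        tips = _measure_jaw(mip, profile, dets, depth, config, config.scan_grid_mm, report)
        report.arch_widths_mm = K.arch_widths(tips)
    return report
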