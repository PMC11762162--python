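import numpy as np
import pytest

from odontometry import PhantomSpec, generate_cbct_phantom, generate_scan_phantom, run_cbct, run_scan
from odontometry.identify import (
    assign_fdi,
    compute_mip,
    detect_teeth_on_mip,
    estimate_midline,
    extract_jaw_profile,
    fixed_midline,
)
from odontometry.io import VoxelVolume

SPACING = 0.3


@pytest.fixture(scope="session")
def cbct_default():
    """Default two-arch CBCT phantom (0.3 mm spacing, 4 mm inter-jaw gap)."""
    spec = PhantomSpec(seed=1)
    vol, truth = generate_cbct_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def cbct_report(cbct_default):
    _, vol, _ = cbct_default
    return run_cbct(vol)


@pytest.fixture(scope="session")
def scan_default():
    spec = PhantomSpec(seed=1)
    cloud, truth = generate_scan_phantom(spec)
    return spec, cloud, truth


@pytest.fixture(scope="session")
def scan_report(scan_default):
    _, cloud, _ = scan_default
    return run_scan(cloud)


def identify_jaw_from_truth(vol, truth, jaw, adaptive=True, threshold=800.0):
    """Identification chain on a ground-truth-masked jaw volume.

    Isolates MIP detection, profile, midline and numbering from the jaw-
    separation stage.
    """
    lab = 1 if jaw == "upper" else 2
    masked = np.where(truth.jaw_labels == lab, vol.intensities, 0.0).astype(np.float32)
    mip = compute_mip(VoxelVolume(masked, vol.spacing), jaw=jaw)
    dets = detect_teeth_on_mip(mip, threshold=threshold)
    profile = extract_jaw_profile(mip, threshold=threshold)
    if adaptive:
        profile = estimate_midline(profile)
    else:
        profile = fixed_midline(profile, center_x=vol.shape[0] / 2.0)
    return assign_fdi(dets, profile), profile, mip


def match_truth(center_mm_2d, truth, jaw):
    """Ground-truth tooth whose centre is nearest a detection centre (mm)."""
    teeth = truth.teeth_of(jaw)
    c = np.asarray(center_mm_2d, dtype=float)
    return teeth[int(np.argmin([np.linalg.norm(t.center[:2] - c) for t in teeth]))]


def numbering_errors(dets, truth, jaw, cell_mm=SPACING):
    """Count detections whose (side, fdi) disagrees with the nearest truth tooth."""
    bad = 0
    for d in dets:
        tt = match_truth(np.asarray(d.center) * cell_mm, truth, jaw)
        if (d.side, d.fdi) != (tt.side, tt.fdi):
            bad += 1
    return bad


@pytest.fixture(scope="session")
def identify_truth():
    return identify_jaw_from_truth


@pytest.fixture(scope="session")
def truth_matcher():
    return match_truth


@pytest.fixture(scope="session")
def numbering_checker():
    return numbering_errors
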