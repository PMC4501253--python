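import numpy as np
import pytest

from crtsync.segments import build_segment_model
from crtsync.synth import (
    SimParams,
    generate_patient,
    make_type1_truth,
    make_type2_truth,
)
from crtsync.wallmotion import compute_delay_map, radial_displacement_curves


@pytest.fixture(scope="session")
def model9():
    return build_segment_model(9)


@pytest.fixture(scope="session")
def clean_type2():
    """Noise-free, translation-free type II patient (no flash)."""
    stack, truth = generate_patient(SimParams(seed=11), make_type2_truth(flash=False))
    return stack, truth


@pytest.fixture(scope="session")
def clean_type1():
    stack, truth = generate_patient(SimParams(seed=12), make_type1_truth())
    return stack, truth


@pytest.fixture(scope="session")
def clean_type2_analysis(clean_type2):
    stack, truth = clean_type2
    curves = radial_displacement_curves(stack)
    delaymap = compute_delay_map(curves)
    return stack, truth, curves, delaymap


def circle_stack(
    radii_per_frame,
    n_slices=3,
    n_points=120,
    translation=None,
    frame_interval_ms=33.0,
    centre_offset=(0.0, 0.0),
):
    """Hand-built stack of concentric-circle contours for geometry tests."""
    from crtsync.wallmotion import ContourStack

    radii_per_frame = np.asarray(radii_per_frame, dtype=float)
    F = len(radii_per_frame)
    theta = np.arange(n_points) * 2 * np.pi / n_points
    unit = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    pts = np.zeros((F, n_slices, n_points, 2))
    T = np.zeros((F, 2)) if translation is None else np.asarray(translation, dtype=float)
    for f in range(F):
        for s in range(n_slices):
            pts[f, s] = radii_per_frame[f] * unit + T[f] + np.asarray(centre_offset)
    slice_z = (np.arange(n_slices) + 0.5) * 8.0
    mitral = np.zeros((F, 3))
    apex = np.zeros((F, 3))
    apex[:, 2] = (n_slices + 0.5) * 8.0
    mitral[:, :2] += T + np.asarray(centre_offset)
    apex[:, :2] += T + np.asarray(centre_offset)
    return ContourStack(
        points=pts,
        mitral_centre=mitral,
        apex=apex,
        slice_z=slice_z,
        frame_interval_ms=frame_interval_ms,
        slice_spacing_mm=8.0,
    )
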