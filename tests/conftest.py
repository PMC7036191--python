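import numpy as np
import pytest
from hypothesis import settings

from corthick import (
    BinaryMask,
    LabelVolume,
    ScalarVolume,
    ThicknessMap,
    compute_tangent_field,
    make_phantom,
    smooth_thickness,
    solve_laplace,
    trace_thickness,
)
from corthick.phantoms import PhantomSpec

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def thickness_from_array(values, valid=None, voxel_size_mm=1.0, smoothed=True):
    """Wrap a raw array as a ThicknessMap (for tests that bypass tracing)."""
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = values > 0
    return ThicknessMap(
        thickness_mm=ScalarVolume(values, voxel_size_mm, valid),
        step_size=0.1,
        smoothed=smoothed,
        truncated_mask=BinaryMask(np.zeros(values.shape, bool), voxel_size_mm),
    )


def compute_thickness(labels: LabelVolume, tolerance=0.1, step_size=0.1,
                      smooth=True, kernel_edge=4) -> ThicknessMap:
    """Full thickness pipeline: solve, tangents, trace, optional smoothing."""
    field = solve_laplace(labels, tolerance=tolerance)
    tangents = compute_tangent_field(field)
    tmap = trace_thickness(labels, tangents, step_size=step_size)
    if smooth:
        tmap = smooth_thickness(tmap, kernel_edge=kernel_edge)
    return tmap


@pytest.fixture(scope="session")
def slab_spec():
    return PhantomSpec("slab", grid_shape=(24, 20, 20), width_voxels=5,
                       inner_offset_voxels=9, voxel_size_mm=1.0)


@pytest.fixture(scope="session")
def slab_volume(slab_spec):
    return make_phantom(slab_spec)


@pytest.fixture(scope="session")
def shell_spec():
    return PhantomSpec("spherical_shell", grid_shape=(36, 36, 36),
                       r1_voxels=8, r2_voxels=12, voxel_size_mm=1.0)


@pytest.fixture(scope="session")
def shell_volume(shell_spec):
    return make_phantom(shell_spec)


@pytest.fixture(scope="session")
def shell_field(shell_volume):
    labels, _ = shell_volume
    return solve_laplace(labels, tolerance=0.1)


@pytest.fixture(scope="session")
def shell_thickness(shell_volume, shell_field):
    labels, _ = shell_volume
    tangents = compute_tangent_field(shell_field)
    return trace_thickness(labels, tangents)
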