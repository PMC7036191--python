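"""Synthetic tissue-label phantoms with analytic ground-truth thickness.

Two geometries emulate the cortical GM ribbon between its WM-GM and
GM-CSF surfaces: a flat slab (parallel plates; field lines are straight)
and a spherical shell (field lines are radial; thickness r2 - r1). Cohorts
apply Gaussian jitter to the geometric boundary parameters — not
voxel-wise noise — so each subject still has an exactly known thickness,
which is what makes parameter-recovery tests possible. Focal "lesions"
displace the GM-CSF boundary outward inside a tapered spherical patch,
mimicking the focal cortical thickening that is the MRI hallmark of FCD.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from corthick.volume_io import CSF, GM, WM, BinaryMask, LabelVolume

_MARGIN = 2  # voxels of clearance the geometry must keep from the grid edge


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry of a single phantom.

    For ``geometry="slab"`` the ribbon is a slab of ``width_voxels``
    perpendicular to ``orientation`` (axis 0/1/2), with WM filling one
    side and CSF the other; ``inner_offset_voxels`` positions the WM-GM
    face (default: centred). For ``geometry="spherical_shell"`` the ribbon
    is the shell ``r1 < r <= r2`` (voxel units) around ``center`` (default:
    grid centre), WM inside, CSF outside.
    """

    geometry: str
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 1.0
    width_voxels: float | None = None
    orientation: int = 0
    inner_offset_voxels: float | None = None
    r1_voxels: float | None = None
    r2_voxels: float | None = None
    center: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if min(self.grid_shape) < 3:
            raise ValueError("grid_shape must be >= 3 per axis")
        if self.geometry == "slab":
            if self.width_voxels is None or self.width_voxels < 2:
                raise ValueError("slab width_voxels must be >= 2")
            if self.orientation not in (0, 1, 2):
                raise ValueError("orientation must be 0, 1 or 2")
            n = self.grid_shape[self.orientation]
            lo = self._inner_offset()
            if lo < _MARGIN or lo + self.width_voxels > n - _MARGIN:
                raise ValueError("slab does not fit in the grid with margin")
        elif self.geometry == "spherical_shell":
            if self.r1_voxels is None or self.r2_voxels is None:
                raise ValueError("shell requires r1_voxels and r2_voxels")
            if not (self.r2_voxels > self.r1_voxels > 2):
                raise ValueError("shell requires r2 > r1 > 2")
            c = np.asarray(self._center())
            shape = np.asarray(self.grid_shape)
            if np.any(c - self.r2_voxels < _MARGIN) or np.any(
                c + self.r2_voxels > shape - 1 - _MARGIN
            ):
                raise ValueError("shell does not fit in the grid with margin")
        else:
            raise ValueError("geometry must be 'slab' or 'spherical_shell'")

    def _inner_offset(self) -> float:
        if self.inner_offset_voxels is not None:
            return self.inner_offset_voxels
        n = self.grid_shape[self.orientation]
        return (n - self.width_voxels) / 2.0

    def _center(self) -> tuple[float, float, float]:
        if self.center is not None:
            return self.center
        return tuple((s - 1) / 2.0 for s in self.grid_shape)

    @property
    def true_thickness_mm(self) -> float:
        if self.geometry == "slab":
            return self.width_voxels * self.voxel_size_mm
        return (self.r2_voxels - self.r1_voxels) * self.voxel_size_mm


@dataclass(frozen=True)
class CohortSpec:
    """A control cohort: one base geometry plus per-subject boundary jitter.

    Both ribbon boundaries are jittered independently with
    N(0, thickness_jitter_sd_voxels), so per-subject true thickness varies
    with SD jitter * sqrt(2) voxels. Defaults emulate a 32-subject
    healthy-control database.
    """

    base: PhantomSpec
    n_subjects: int = 32
    thickness_jitter_sd_voxels: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("cohort needs at least 2 subjects")
        if self.thickness_jitter_sd_voxels < 0:
            raise ValueError("jitter must be non-negative")


@dataclass(frozen=True)
class CohortSubject:
    """One simulated control: labels plus its exact constructed thickness."""

    labels: LabelVolume
    true_thickness_mm: float


@dataclass(frozen=True)
class LesionSpec:
    """A focal thickening: the GM-CSF boundary moves outward by up to
    ``thickening_voxels`` inside a sphere of ``radius_voxels`` around
    ``center``, with a cosine taper over ``taper_voxels`` at the rim."""

    center: tuple[float, float, float]
    radius_voxels: float
    thickening_voxels: float
    taper_voxels: float = 2.0

    def __post_init__(self) -> None:
        if self.thickening_voxels < 0:
            raise ValueError("thickening must be non-negative")
        if self.radius_voxels <= 0:
            raise ValueError("radius must be positive")
        if not (0 < self.taper_voxels <= self.radius_voxels):
            raise ValueError("taper must be in (0, radius]")


def _coords(shape: tuple[int, int, int]):
    return np.meshgrid(*(np.arange(s, dtype=np.float64) for s in shape), indexing="ij")


def make_phantom(spec: PhantomSpec) -> tuple[LabelVolume, float]:
    """Build the label volume for a spec; returns it with the constructed
    ground-truth thickness in mm."""
    labels = np.full(spec.grid_shape, CSF, dtype=np.int32)
    if spec.geometry == "slab":
        ax = np.arange(spec.grid_shape[spec.orientation], dtype=np.float64)
        lo = spec._inner_offset()
        hi = lo + spec.width_voxels
        line = np.where(ax < lo, WM, np.where(ax < hi, GM, CSF)).astype(np.int32)
        shape = [1, 1, 1]
        shape[spec.orientation] = -1
        labels = np.broadcast_to(line.reshape(shape), spec.grid_shape).copy()
    else:
        x, y, z = _coords(spec.grid_shape)
        cx, cy, cz = spec._center()
        r = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        labels[r <= spec.r1_voxels] = WM
        labels[(r > spec.r1_voxels) & (r <= spec.r2_voxels)] = GM
    return LabelVolume(labels, spec.voxel_size_mm), spec.true_thickness_mm


def make_cohort(spec: CohortSpec) -> list[CohortSubject]:
    """Simulate a control cohort by jittering both boundary positions.

    Deterministic under ``spec.seed``: the same spec always produces
    bit-identical volumes.
    """
    rng = np.random.default_rng(spec.seed)
    base = spec.base
    subjects: list[CohortSubject] = []
    for _ in range(spec.n_subjects):
        d_in, d_out = rng.normal(0.0, spec.thickness_jitter_sd_voxels, size=2)
        if base.geometry == "slab":
            lo = base._inner_offset() + d_in
            width = (base._inner_offset() + base.width_voxels + d_out) - lo
            sub = replace(base, inner_offset_voxels=lo, width_voxels=width)
        else:
            sub = replace(
                base,
                r1_voxels=base.r1_voxels + d_in,
                r2_voxels=base.r2_voxels + d_out,
            )
        vol, truth = make_phantom(sub)
        subjects.append(CohortSubject(labels=vol, true_thickness_mm=truth))
    return subjects


def inject_lesion(
    labels: LabelVolume, lesion: LesionSpec
) -> tuple[LabelVolume, BinaryMask]:
    """Thicken the ribbon inside a tapered spherical patch.

    CSF voxels whose Euclidean distance to the existing GM ribbon is at
    most the local displacement delta(p) are relabelled GM, which pushes
    the GM-CSF surface outward by ``thickening_voxels`` in the patch core.
    The returned ground-truth mask is the set of (new) GM voxels inside
    the patch sphere, i.e. the voxels whose column thickness was raised.

    Raises if the patch sphere misses the GM ribbon entirely. A zero
    thickening is a null lesion: unchanged labels, empty mask.
    """
    shape = labels.shape
    c = np.asarray(lesion.center, dtype=np.float64)
    if np.any(c < 0) or np.any(c > np.asarray(shape) - 1):
        raise ValueError("lesion center lies outside the grid")
    x, y, z = _coords(shape)
    d = np.sqrt((x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2)

    # cosine taper: full displacement in the core, smooth falloff at the rim
    core = lesion.radius_voxels - lesion.taper_voxels
    ramp = np.clip((lesion.radius_voxels - d) / lesion.taper_voxels, 0.0, 1.0)
    taper = np.where(d <= core, 1.0, 0.5 * (1.0 - np.cos(np.pi * ramp)))
    taper[d > lesion.radius_voxels] = 0.0
    delta = lesion.thickening_voxels * taper

    gm = labels.gm_mask
    if not (gm & (d <= lesion.radius_voxels)).any():
        raise ValueError("lesion patch does not intersect the GM ribbon")
    if lesion.thickening_voxels == 0:
        return labels, BinaryMask(np.zeros(shape, dtype=bool), labels.voxel_size_mm)

    dist_to_gm = ndimage.distance_transform_edt(~gm)
    grow = (labels.labels == CSF) & (dist_to_gm <= delta)
    new_labels = labels.labels.copy()
    new_labels[grow] = GM
    out = LabelVolume(new_labels, labels.voxel_size_mm)
    truth = (out.labels == GM) & (delta > 0)
    return out, BinaryMask(truth, labels.voxel_size_mm)
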