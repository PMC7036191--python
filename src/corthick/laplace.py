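"""Laplace-equation cortical thickness on a tissue-labelled voxel grid.

The grey-matter ribbon is treated as the interior of a boundary-value
problem for the harmonic potential psi: the WM side of the ribbon is held
at psi = 0, everything beyond the GM-CSF surface (CSF and background
alike) at psi = 256, and psi on GM solves the discrete Laplace equation
via Jacobi iteration (each GM voxel replaced by the mean of its six
face-neighbours). Field lines of the normalized potential gradient run
from the inner to the outer surface without crossing; the length of the
field line through a voxel — measured by bidirectional sub-voxel Euler
integration — is its cortical thickness.

Coordinates are voxel-index space (0-based); a continuous position is
"in" the tissue class of its nearest voxel. Thickness in mm is
``(forward_steps + backward_steps) * step_size * voxel_size_mm``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from corthick.volume_io import GM, WM, BinaryMask, LabelVolume, ScalarVolume

#: Dirichlet boundary values of the potential.
PSI_INNER = 0.0
PSI_OUTER = 256.0

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


class NotConvergedError(RuntimeError):
    """The Jacobi solver hit its iteration cap above tolerance."""


class EmptyDomainError(ValueError):
    """The label volume contains no grey-matter voxels."""


@dataclass
class PotentialField:
    """Converged (or capped) solution of the ribbon boundary-value problem.

    ``psi.values`` is defined on the full grid: 0 on WM, 256 on all
    non-GM/non-WM voxels, and the Jacobi solution on GM. ``unreachable_mask``
    marks GM components that do not touch both boundary classes; thickness
    is undefined there.
    """

    psi: ScalarVolume
    gm_mask: BinaryMask
    iterations_run: int
    final_epsilon: float
    converged: bool
    unreachable_mask: BinaryMask
    epsilon_history: list[float] = field(default_factory=list)
    boundary_lo: float = PSI_INNER
    boundary_hi: float = PSI_OUTER


@dataclass
class TangentField:
    """Unit tangent of the potential's field lines, per voxel.

    Components are stored on the full grid so that trilinear interpolation
    at fractional trace positions is well defined near the ribbon edge;
    they are meaningful (unit norm) wherever ``undefined_mask`` is False.
    """

    tx: np.ndarray
    ty: np.ndarray
    tz: np.ndarray
    gm_mask: BinaryMask
    undefined_mask: BinaryMask
    gradient_floor: float


@dataclass
class ThicknessMap:
    """Per-GM-voxel cortical thickness in mm."""

    thickness_mm: ScalarVolume
    step_size: float
    smoothed: bool
    truncated_mask: BinaryMask

    @property
    def voxel_size_mm(self) -> float:
        return self.thickness_mm.voxel_size_mm

    @property
    def valid_mask(self) -> np.ndarray:
        return self.thickness_mm.valid_mask


def _neighbour_mean(psi: np.ndarray) -> np.ndarray:
    # Replicate-padding makes a grid-edge neighbour equal to the voxel
    # itself; GM never touches the grid edge in well-posed inputs.
    p = np.pad(psi, 1, mode="edge")
    return (
        p[2:, 1:-1, 1:-1] + p[:-2, 1:-1, 1:-1]
        + p[1:-1, 2:, 1:-1] + p[1:-1, :-2, 1:-1]
        + p[1:-1, 1:-1, 2:] + p[1:-1, 1:-1, :-2]
    ) / 6.0


def _unreachable_components(labels: LabelVolume) -> np.ndarray:
    """GM components lacking a face-neighbour path to both boundary classes."""
    gm = labels.gm_mask
    comp, n = ndimage.label(gm, structure=_FACE_STRUCT)
    wm = labels.wm_mask
    outer = ~gm & ~wm
    bad = np.zeros_like(gm)
    for i, sl in enumerate(ndimage.find_objects(comp), start=1):
        sl = tuple(slice(max(s.start - 1, 0), s.stop + 1) for s in sl)
        c = comp[sl] == i
        grown = ndimage.binary_dilation(c, structure=_FACE_STRUCT)
        if not (grown & wm[sl]).any() or not (grown & outer[sl]).any():
            bad[sl] |= c
    return bad


def solve_laplace(
    labels: LabelVolume,
    tolerance: float = 0.1,
    max_iterations: int = 20000,
    init_value: float = 128.0,
    stat: str = "max",
) -> PotentialField:
    """Solve the discrete Laplace equation on the GM ribbon by Jacobi iteration.

    Each sweep simultaneously replaces every GM voxel by the arithmetic
    mean of its six face-neighbours, with WM fixed at 0 and all other
    non-GM voxels fixed at 256. Iteration stops when the per-sweep change
    statistic over GM voxels (``max`` of |delta psi| by default, or
    ``mean``) drops below ``tolerance``.

    Parameters
    ----------
    tolerance:
        Convergence threshold on the per-sweep change statistic (potential
        units, default 0.1).
    init_value:
        Initial GM potential; 128 (the boundary midpoint) speeds
        convergence and does not affect the fixed point.
    stat:
        Aggregation of per-voxel changes: ``"max"`` (strict) or ``"mean"``.

    Raises
    ------
    EmptyDomainError
        If the volume has no GM voxels.
    """
    if stat not in ("max", "mean"):
        raise ValueError("stat must be 'max' or 'mean'")
    gm = labels.gm_mask
    if not gm.any():
        raise EmptyDomainError("label volume contains no GM voxels")
    wm = labels.wm_mask

    unreachable = _unreachable_components(labels)
    if unreachable.any():
        warnings.warn(
            f"{int(unreachable.sum())} GM voxels lie in components not touching "
            "both boundaries; thickness is undefined there",
            stacklevel=2,
        )

    psi = np.where(gm, float(init_value), np.where(wm, PSI_INNER, PSI_OUTER))
    history: list[float] = []
    eps = np.inf
    it = 0
    agg = np.max if stat == "max" else np.mean
    while it < max_iterations:
        nb = _neighbour_mean(psi)
        new = np.where(gm, nb, psi)
        eps = float(agg(np.abs(new[gm] - psi[gm])))
        psi = new
        it += 1
        history.append(eps)
        if eps < tolerance:
            break
    converged = eps < tolerance

    vsz = labels.voxel_size_mm
    return PotentialField(
        psi=ScalarVolume(psi, vsz, np.ones_like(gm)),
        gm_mask=BinaryMask(gm, vsz),
        iterations_run=it,
        final_epsilon=eps,
        converged=converged,
        unreachable_mask=BinaryMask(unreachable, vsz),
        epsilon_history=history,
    )


def compute_tangent_field(
    field: PotentialField,
    gradient_floor: float = 1e-6,
    force: bool = False,
) -> TangentField:
    """Normalized gradient of the potential: the field-line unit tangent.

    The gradient uses central differences ``[psi(x+1) - psi(x-1)] / 2``
    per axis (one-sided at grid edges) and is divided by its Euclidean
    norm. GM voxels whose gradient norm falls below ``gradient_floor``
    (plateaus) are flagged undefined rather than divided by zero.
    """
    if not field.converged and not force:
        raise NotConvergedError(
            "potential field did not converge; pass force=True to override"
        )
    psi = field.psi.values
    gx, gy, gz = np.gradient(psi)
    norm = np.sqrt(gx * gx + gy * gy + gz * gz)
    ok = norm >= gradient_floor
    inv = np.zeros_like(norm)
    inv[ok] = 1.0 / norm[ok]
    gm = field.gm_mask.mask
    undefined = (gm & ~ok) | field.unreachable_mask.mask
    vsz = field.psi.voxel_size_mm
    return TangentField(
        tx=gx * inv,
        ty=gy * inv,
        tz=gz * inv,
        gm_mask=BinaryMask(gm, vsz),
        undefined_mask=BinaryMask(undefined, vsz),
        gradient_floor=gradient_floor,
    )


def _trace_one_way(
    components: tuple[np.ndarray, np.ndarray, np.ndarray],
    labels_arr: np.ndarray,
    seeds: np.ndarray,
    sign: float,
    step_size: float,
    max_steps: int,
    gradient_floor: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Euler-integrate all seeds until their position leaves GM.

    Returns (steps, truncated, failed): step counts, traces that hit the
    cap, and traces whose interpolated tangent vanished mid-path.
    """
    tx, ty, tz = components
    shape = labels_arr.shape
    hi = np.array(shape, dtype=np.float64) - 1.0
    n = len(seeds)
    pos = seeds.astype(np.float64)
    steps = np.zeros(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    failed = np.zeros(n, dtype=bool)

    for _ in range(max_steps):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        p = pos[idx].T
        vx = ndimage.map_coordinates(tx, p, order=1, mode="nearest")
        vy = ndimage.map_coordinates(ty, p, order=1, mode="nearest")
        vz = ndimage.map_coordinates(tz, p, order=1, mode="nearest")
        norm = np.sqrt(vx * vx + vy * vy + vz * vz)
        dead = norm < gradient_floor
        if dead.any():
            failed[idx[dead]] = True
            active[idx[dead]] = False
            idx = idx[~dead]
            if idx.size == 0:
                continue
            vx, vy, vz, norm = vx[~dead], vy[~dead], vz[~dead], norm[~dead]
        scale = sign * step_size / norm
        pos[idx, 0] = np.clip(pos[idx, 0] + vx * scale, 0.0, hi[0])
        pos[idx, 1] = np.clip(pos[idx, 1] + vy * scale, 0.0, hi[1])
        pos[idx, 2] = np.clip(pos[idx, 2] + vz * scale, 0.0, hi[2])
        steps[idx] += 1
        ri = np.rint(pos[idx]).astype(np.intp)
        lbl = labels_arr[ri[:, 0], ri[:, 1], ri[:, 2]]
        active[idx[lbl != GM]] = False

    return steps, active.copy(), failed


def trace_thickness(
    labels: LabelVolume,
    tangents: TangentField,
    step_size: float = 0.1,
    max_steps: int | None = None,
) -> ThicknessMap:
    """Bidirectional field-line tracing from every GM voxel.

    From each GM voxel two Euler traces are run: forward along +T until
    the position leaves GM through the outer (CSF/outside) surface, and
    backward along -T until it leaves into WM. The tangent at fractional
    positions is obtained by componentwise trilinear interpolation and
    renormalized. Thickness is the total step count times ``step_size``
    times the voxel size in mm.

    Traces exceeding ``max_steps`` (default ``10 * grid_diagonal /
    step_size``) are flagged in ``truncated_mask`` and their voxel is
    invalid, as are voxels whose tangent is undefined at the seed or
    vanishes mid-trace.
    """
    if not (0 < step_size <= 1):
        raise ValueError("step_size must lie in (0, 1]")
    gm = labels.gm_mask
    if gm.shape != tangents.gm_mask.shape:
        raise ValueError("labels and tangent field grids differ")
    if max_steps is None:
        diag = float(np.linalg.norm(labels.shape))
        max_steps = int(np.ceil(10.0 * diag / step_size))

    seeds_ok = gm & ~tangents.undefined_mask.mask
    seeds = np.argwhere(seeds_ok)
    comps = (tangents.tx, tangents.ty, tangents.tz)
    fwd, fwd_trunc, fwd_fail = _trace_one_way(
        comps, labels.labels, seeds, +1.0, step_size, max_steps, tangents.gradient_floor
    )
    bwd, bwd_trunc, bwd_fail = _trace_one_way(
        comps, labels.labels, seeds, -1.0, step_size, max_steps, tangents.gradient_floor
    )

    good = ~(fwd_trunc | bwd_trunc | fwd_fail | bwd_fail)
    thickness = np.zeros(labels.shape, dtype=np.float64)
    valid = np.zeros(labels.shape, dtype=bool)
    truncated = np.zeros(labels.shape, dtype=bool)
    ix, iy, iz = seeds[:, 0], seeds[:, 1], seeds[:, 2]
    total_mm = (fwd + bwd) * step_size * labels.voxel_size_mm
    thickness[ix[good], iy[good], iz[good]] = total_mm[good]
    valid[ix[good], iy[good], iz[good]] = True
    trunc = fwd_trunc | bwd_trunc
    truncated[ix[trunc], iy[trunc], iz[trunc]] = True

    vsz = labels.voxel_size_mm
    return ThicknessMap(
        thickness_mm=ScalarVolume(thickness, vsz, valid),
        step_size=step_size,
        smoothed=False,
        truncated_mask=BinaryMask(truncated, vsz),
    )


def smooth_thickness(
    tmap: ThicknessMap,
    kernel_edge: int = 4,
    anchor: str = "low",
) -> ThicknessMap:
    """Mask-normalized box smoothing of a thickness map.

    Each valid voxel becomes the mean of the valid-voxel values inside its
    ``kernel_edge``-cubed window; invalid and non-GM voxels carry zero
    weight, so ribbon-edge thickness is not diluted toward zero. An
    even-sized window has no centre voxel: ``anchor="low"`` covers offsets
    {-k/2, ..., k/2 - 1} per axis (``"high"`` the mirror image).
    """
    if tmap.smoothed:
        raise ValueError("thickness map is already smoothed")
    if kernel_edge < 1:
        raise ValueError("kernel_edge must be >= 1")
    if kernel_edge > min(tmap.thickness_mm.shape):
        raise ValueError("kernel larger than grid")
    if anchor not in ("low", "high"):
        raise ValueError("anchor must be 'low' or 'high'")

    vals = np.where(tmap.valid_mask, tmap.thickness_mm.values, 0.0)
    w = tmap.valid_mask.astype(np.float64)
    kernel = np.ones((kernel_edge,) * 3)
    origin = 0 if anchor == "low" else (-1 if kernel_edge % 2 == 0 else 0)
    num = ndimage.correlate(vals, kernel, mode="constant", cval=0.0, origin=origin)
    den = ndimage.correlate(w, kernel, mode="constant", cval=0.0, origin=origin)
    out = np.zeros_like(vals)
    ok = tmap.valid_mask & (den > 0)
    out[ok] = num[ok] / den[ok]

    return ThicknessMap(
        thickness_mm=ScalarVolume(out, tmap.voxel_size_mm, ok),
        step_size=tmap.step_size,
        smoothed=True,
        truncated_mask=tmap.truncated_mask,
    )


def regional_mean_thickness(
    tmap: ThicknessMap, region: BinaryMask
) -> tuple[float, float, int]:
    """Mean and sample SD of valid thickness values inside a region mask.

    Returns ``(mean, sd, n_voxels)``; the SD is the n-1 sample SD, and 0.0
    by convention for a single-voxel region.
    """
    if region.shape != tmap.thickness_mm.shape:
        raise ValueError("region grid does not match thickness map")
    sel = region.mask & tmap.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise ValueError("region does not overlap the valid thickness mask")
    vals = tmap.thickness_mm.values[sel]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, n
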