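"""NIfTI I/O and the in-memory volume containers shared by the pipeline.

All volumes live on isotropic voxel grids. Tissue labels use a fixed code
scheme: 0 = background/air, 1 = white matter (WM), 2 = grey matter (GM),
3 = CSF / outside-cortex. A remap table at ingest translates other label
dialects (e.g. thresholded SPM c1/c2/c3 outputs) into this scheme.

Scalar volumes (thickness, potential, mean/SD, z-score) carry an explicit
validity mask; on disk invalid voxels are stored as 0, so the mask of a
thickness-like map (strictly positive where defined) is recoverable as the
nonzero support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

#: Tissue label codes used throughout the package.
BACKGROUND = 0
WM = 1
GM = 2
CSF = 3

_VALID_LABELS = frozenset({BACKGROUND, WM, GM, CSF})

#: Relative tolerance for the isotropy check on voxel spacing.
ISOTROPY_RTOL = 1e-3


class AnisotropicVoxelError(ValueError):
    """Voxel spacing is not isotropic; resample upstream before ingest."""


class LabelCodeError(ValueError):
    """A voxel carries a label code outside {0, 1, 2, 3} after remapping."""


def _check_grid(arr: np.ndarray, name: str) -> None:
    if arr.ndim != 3:
        raise ValueError(f"{name} must be 3D, got ndim={arr.ndim}")
    if min(arr.shape) < 3:
        raise ValueError(f"{name} must be at least 3 voxels per axis, got {arr.shape}")


@dataclass
class LabelVolume:
    """A 3D tissue-class grid with isotropic voxel size in mm."""

    labels: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("labels must be an integer array")
        _check_grid(self.labels, "labels")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        present = set(np.unique(self.labels).tolist())
        if not present <= _VALID_LABELS:
            raise LabelCodeError(f"unexpected label codes: {sorted(present - _VALID_LABELS)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def tissue_mask(self, code: int) -> np.ndarray:
        return self.labels == code

    @property
    def gm_mask(self) -> np.ndarray:
        return self.labels == GM

    @property
    def wm_mask(self) -> np.ndarray:
        return self.labels == WM


@dataclass
class ScalarVolume:
    """A 3D floating-point field with an explicit validity mask."""

    values: np.ndarray
    voxel_size_mm: float
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        _check_grid(self.values, "values")
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask shapes differ")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("non-finite values inside valid_mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class BinaryMask:
    """A 3D boolean grid sharing the pipeline's grid contract."""

    mask: np.ndarray
    voxel_size_mm: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        _check_grid(self.mask, "mask")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _isotropic_voxel_size(img: nib.Nifti1Image, path) -> float:
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    ref = float(zooms[0])
    if ref <= 0 or np.any(np.abs(zooms - ref) > ISOTROPY_RTOL * ref):
        raise AnisotropicVoxelError(
            f"{path}: voxel spacing {tuple(zooms)} is not isotropic; "
            "resample before ingest"
        )
    return ref


def read_label_volume(path, label_mapping: dict[int, int] | None = None) -> LabelVolume:
    """Read a tissue-label NIfTI, optionally remapping its label codes.

    Parameters
    ----------
    path:
        NIfTI file whose voxels are integer tissue codes.
    label_mapping:
        Optional ``{file_code: canonical_code}`` table applied before
        validation. Codes absent from the table are left unchanged, so a
        partial table remaps only the dialect-specific codes.

    Raises
    ------
    AnisotropicVoxelError
        If the header voxel spacing is not isotropic within 1e-3 relative.
    LabelCodeError
        If, after remapping, any voxel is outside {0, 1, 2, 3}.
    """
    img = nib.load(str(path))
    voxel_size = _isotropic_voxel_size(img, path)
    data = np.asarray(img.dataobj)
    labels = np.rint(data).astype(np.int32)
    if label_mapping:
        out = labels.copy()
        for src, dst in label_mapping.items():
            out[labels == src] = dst
        labels = out
    return LabelVolume(labels=labels, voxel_size_mm=voxel_size)


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def write_label_volume(vol: LabelVolume, path) -> Path:
    img = nib.Nifti1Image(vol.labels.astype(np.int16), _affine(vol.voxel_size_mm))
    img.header.set_zooms((vol.voxel_size_mm,) * 3)
    nib.save(img, str(path))
    return Path(path)


def write_scalar_volume(vol: ScalarVolume, path) -> Path:
    """Write a scalar volume as float64 NIfTI; invalid voxels stored as 0."""
    data = np.where(vol.valid_mask, vol.values, 0.0)
    img = nib.Nifti1Image(data.astype(np.float64), _affine(vol.voxel_size_mm))
    img.header.set_zooms((vol.voxel_size_mm,) * 3)
    nib.save(img, str(path))
    return Path(path)


def read_scalar_volume(path, valid_mask: np.ndarray | None = None) -> ScalarVolume:
    """Read a scalar NIfTI written by :func:`write_scalar_volume`.

    If ``valid_mask`` is not supplied the nonzero support is used, which is
    exact for strictly-positive maps (thickness, SD) stored with the
    0-means-invalid convention.
    """
    img = nib.load(str(path))
    voxel_size = _isotropic_voxel_size(img, path)
    values = np.asarray(img.dataobj, dtype=np.float64)
    if valid_mask is None:
        valid_mask = values != 0
    return ScalarVolume(values=values, voxel_size_mm=voxel_size, valid_mask=np.asarray(valid_mask, bool))


def write_binary_mask(mask: BinaryMask, path) -> Path:
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.voxel_size_mm))
    img.header.set_zooms((mask.voxel_size_mm,) * 3)
    nib.save(img, str(path))
    return Path(path)


def read_binary_mask(path) -> BinaryMask:
    img = nib.load(str(path))
    voxel_size = _isotropic_voxel_size(img, path)
    data = np.asarray(img.dataobj)
    return BinaryMask(mask=data > 0.5, voxel_size_mm=voxel_size)
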