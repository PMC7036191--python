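"""Normative thickness template, z-score extension map, lesion clusters.

A cohort of smoothed control thickness maps yields voxel-wise mean and
sample-SD images; a patient's smoothed map is converted to the z-score
"extension map" z = (patient - mean) / SD, and candidate lesions are the
connected supra-threshold clusters exceeding a minimum voxel count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from corthick.laplace import ThicknessMap
from corthick.volume_io import (
    BinaryMask,
    ScalarVolume,
    read_scalar_volume,
    write_scalar_volume,
)


@dataclass
class TemplateStats:
    """Voxel-wise mean/SD thickness over a healthy-control cohort."""

    mean_map: ScalarVolume
    sd_map: ScalarVolume
    n_controls: int
    sd_floor: float
    kernel_edge: int | None = None

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("template requires at least 2 controls")
        if np.any(self.sd_map.values[self.sd_map.valid_mask] < 0):
            raise ValueError("negative SD in template")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.mean_map.valid_mask


@dataclass
class ExtensionMap:
    """Voxel-wise z-scores of a patient against the normative template."""

    z: ScalarVolume
    patient_id: str = ""


@dataclass
class LesionCluster:
    voxels: np.ndarray  # (n, 3) voxel coordinates
    size: int
    peak_z: float
    centroid: tuple[float, float, float]


@dataclass
class LesionClusterSet:
    clusters: list[LesionCluster]
    detection_mask: BinaryMask
    z_threshold: float
    min_cluster_voxels: int
    connectivity: int

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": i + 1,
                "size_voxels": c.size,
                "peak_z": c.peak_z,
                "centroid_x": c.centroid[0],
                "centroid_y": c.centroid[1],
                "centroid_z": c.centroid[2],
            }
            for i, c in enumerate(self.clusters)
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "cluster_id", "size_voxels", "peak_z",
                "centroid_x", "centroid_y", "centroid_z",
            ],
        )


def build_template(
    control_maps: list[ThicknessMap],
    min_coverage: float = 0.75,
    sd_floor: float = 1e-3,
) -> TemplateStats:
    """Voxel-wise mean and sample SD over a cohort of smoothed maps.

    A voxel enters the template only if at least ``min_coverage`` of the
    controls (and at least two) have a valid thickness there; GM masks of
    independently processed subjects rarely coincide exactly at the ribbon
    edge.
    """
    n = len(control_maps)
    if n < 2:
        raise ValueError("need at least 2 control maps")
    ref = control_maps[0]
    for m in control_maps:
        if m.thickness_mm.shape != ref.thickness_mm.shape:
            raise ValueError("control maps are on different grids")
        if not np.isclose(m.voxel_size_mm, ref.voxel_size_mm, rtol=1e-6):
            raise ValueError("control maps have different voxel sizes")
        if not m.smoothed:
            raise ValueError("control maps must be smoothed before templating")

    vals = np.stack([m.thickness_mm.values for m in control_maps])
    msk = np.stack([m.valid_mask for m in control_maps])
    count = msk.sum(axis=0)
    need = max(2, int(np.ceil(min_coverage * n)))
    valid = count >= need

    w = msk.astype(np.float64)
    cnt = np.maximum(count, 1)
    mean = (vals * w).sum(axis=0) / cnt
    var = ((vals - mean) ** 2 * w).sum(axis=0) / np.maximum(cnt - 1, 1)
    sd = np.sqrt(var)
    mean[~valid] = 0.0
    sd[~valid] = 0.0

    vsz = ref.voxel_size_mm
    return TemplateStats(
        mean_map=ScalarVolume(mean, vsz, valid),
        sd_map=ScalarVolume(sd, vsz, valid),
        n_controls=n,
        sd_floor=sd_floor,
    )


def extension_map(
    patient: ThicknessMap,
    template: TemplateStats,
    patient_id: str = "",
) -> ExtensionMap:
    """z = (patient - mean) / SD wherever the SD is above its floor.

    Voxels where the template SD falls below ``template.sd_floor`` (or
    where either input is invalid) are marked invalid rather than mapped
    to +/-infinity.
    """
    if patient.thickness_mm.shape != template.mean_map.shape:
        raise ValueError("patient and template grids differ")
    if not patient.smoothed:
        raise ValueError("patient thickness map must be smoothed")
    sd = template.sd_map.values
    valid = (
        patient.valid_mask
        & template.valid_mask
        & (sd >= template.sd_floor)
    )
    z = np.zeros_like(sd)
    z[valid] = (
        patient.thickness_mm.values[valid] - template.mean_map.values[valid]
    ) / sd[valid]
    return ExtensionMap(
        z=ScalarVolume(z, patient.voxel_size_mm, valid),
        patient_id=patient_id,
    )


_CONN_STRUCT = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def detect_lesions(
    zmap: ExtensionMap,
    z_threshold: float = 3.0,
    min_cluster_voxels: int = 3,
    connectivity: int = 6,
    strict_cluster_rule: bool = True,
) -> LesionClusterSet:
    """Threshold the extension map and keep large-enough clusters.

    Voxels with z strictly greater than ``z_threshold`` are candidate
    lesion voxels; connected components (face adjacency by default) whose
    voxel count is strictly greater than ``min_cluster_voxels`` (>= with
    ``strict_cluster_rule=False``) form the detected lesion set, sorted by
    peak z descending. An empty result is a valid outcome.
    """
    if connectivity not in _CONN_STRUCT:
        raise ValueError("connectivity must be 6, 18 or 26")
    z = zmap.z.values
    supra = zmap.z.valid_mask & (z > z_threshold)
    lab, n = ndimage.label(supra, structure=_CONN_STRUCT[connectivity])
    clusters: list[LesionCluster] = []
    detection = np.zeros_like(supra)
    if n:
        sizes = np.bincount(lab.ravel())[1:]
        for i in range(1, n + 1):
            size = int(sizes[i - 1])
            keep = size > min_cluster_voxels if strict_cluster_rule else size >= min_cluster_voxels
            if not keep:
                continue
            coords = np.argwhere(lab == i)
            zs = z[coords[:, 0], coords[:, 1], coords[:, 2]]
            clusters.append(
                LesionCluster(
                    voxels=coords,
                    size=size,
                    peak_z=float(zs.max()),
                    centroid=tuple(coords.mean(axis=0)),
                )
            )
            detection[lab == i] = True
    clusters.sort(key=lambda c: c.peak_z, reverse=True)
    return LesionClusterSet(
        clusters=clusters,
        detection_mask=BinaryMask(detection, zmap.z.voxel_size_mm),
        z_threshold=z_threshold,
        min_cluster_voxels=min_cluster_voxels,
        connectivity=connectivity,
    )


def save_template(template: TemplateStats, prefix) -> tuple[Path, Path, Path]:
    """Persist a template as mean/SD NIfTIs plus a JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mean_path = prefix.with_name(prefix.name + "_mean.nii.gz")
    sd_path = prefix.with_name(prefix.name + "_sd.nii.gz")
    meta_path = prefix.with_name(prefix.name + "_template.json")
    write_scalar_volume(template.mean_map, mean_path)
    write_scalar_volume(template.sd_map, sd_path)
    meta = {
        "n_controls": template.n_controls,
        "sd_floor": template.sd_floor,
        "kernel_edge": template.kernel_edge,
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return mean_path, sd_path, meta_path


def load_template(prefix) -> TemplateStats:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_name(prefix.name + "_template.json").read_text())
    mean = read_scalar_volume(prefix.with_name(prefix.name + "_mean.nii.gz"))
    # mean and SD share a valid mask; the mean's nonzero support defines it
    sd = read_scalar_volume(
        prefix.with_name(prefix.name + "_sd.nii.gz"), valid_mask=mean.valid_mask
    )
    return TemplateStats(
        mean_map=mean,
        sd_map=sd,
        n_controls=int(meta["n_controls"]),
        sd_floor=float(meta["sd_floor"]),
        kernel_edge=meta.get("kernel_edge"),
    )
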