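"""Cohort frequency heatmaps and report-slice extraction.

A heatmap is the voxelwise count of overlapping segmentations divided by the
group size N, so every value lies on the lattice {0, 1/n, ..., 1}. Report
slices are selected by world coordinate: the plane of voxel centers nearest
to the requested mm position along the slicing axis (z for axial, y for
coronal, RAS+), with midway ties resolved to the lower voxel index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._errors import GeometryError
from .grids import BinaryMask, ProbabilityVolume, VolumeGrid, write_volume

__all__ = ["HeatmapVolume", "cumulative_heatmap", "slice_at_mm", "write_heatmap"]

_AXIS_INDEX = {"axial": 2, "coronal": 1}


@dataclass(frozen=True)
class HeatmapVolume:
    """A segmentation-frequency volume with its normalization count n."""

    grid: ProbabilityVolume
    n: int

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine


def cumulative_heatmap(masks: list[BinaryMask]) -> HeatmapVolume:
    """Voxelwise sum of binary masks divided by the number of masks."""
    if not masks:
        raise ValueError("need at least one mask")
    ref = masks[0]
    acc = np.zeros(ref.grid.shape, dtype=np.float64)
    for m in masks:
        if m.grid.shape != ref.grid.shape or not np.allclose(
            m.affine, ref.affine, atol=1e-4
        ):
            raise GeometryError("heatmap masks are not on a common grid")
        acc += m.data
    acc /= len(masks)
    return HeatmapVolume(
        grid=ProbabilityVolume(grid=VolumeGrid(acc, ref.affine)),
        n=len(masks),
    )


def slice_at_mm(
    hm: HeatmapVolume | VolumeGrid,
    axis: str,
    coordinate_mm: float,
) -> tuple[np.ndarray, int]:
    """Extract the plane nearest a world coordinate along an axis.

    Returns the 2-D array and the chosen voxel index along the slicing axis.
    Midway ties pick the lower index.
    """
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of {sorted(_AXIS_INDEX)}, got {axis!r}")
    grid = hm.grid.grid if isinstance(hm, HeatmapVolume) else hm
    ax = _AXIS_INDEX[axis]
    inv = np.linalg.inv(grid.affine)
    # world positions of plane centers along the axis; assumes the template
    # is axis-aligned (true of MNI grids), so only the target world component
    # matters for the continuous voxel coordinate along that axis
    point = np.zeros(4)
    point[ax] = coordinate_mm
    point[3] = 1.0
    cont = (inv @ point)[ax]
    n = grid.shape[ax]
    if cont < -0.5 or cont > n - 0.5:
        raise ValueError(
            f"{coordinate_mm} mm lies outside the template extent along {axis}"
        )
    # nearest plane, ties at .5 to the lower index
    idx = int(np.ceil(cont - 0.5))
    idx = min(max(idx, 0), n - 1)
    plane = np.take(grid.data, idx, axis=ax)
    return plane, idx


def write_heatmap(
    hm: HeatmapVolume,
    path: str | Path,
    group_label: str = "",
) -> Path:
    """Write the heatmap as 32-bit float NIfTI plus a JSON sidecar with n."""
    path = Path(path)
    write_volume(hm.grid, path)
    stem = path.name[: -len(".nii.gz")] if path.name.endswith(".nii.gz") else path.stem
    sidecar = path.parent / f"{stem}.json"
    sidecar.write_text(
        json.dumps({"n": hm.n, "group": group_label}, indent=2) + "\n"
    )
    return path
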