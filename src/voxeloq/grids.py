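"""NIfTI-1 volume I/O and voxel/world geometry.

All volumes in this package are carried by :class:`VolumeGrid`: a 3-D scalar
array plus a 4×4 voxel-index → world-mm affine in RAS+ orientation (right,
anterior, superior are the positive axes; "left hemisphere" is negative world
x on standard MNI templates). Volumes read from disk are reoriented to the
closest RAS+ canonical orientation so that hemisphere handling downstream is
unambiguous. Voxel indices are 0-based and a voxel's world position is the
position of its center.

Physical volumes are always in mm³: the voxel volume is the absolute
determinant of the affine's 3×3 part, and a binary mask's volume is its
foreground voxel count times that.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from ._errors import DimensionalityError, GeometryError

__all__ = [
    "VolumeGrid",
    "BinaryMask",
    "LabelVolume",
    "ProbabilityVolume",
    "read_volume",
    "write_volume",
    "voxel_volume_mm3",
    "mask_volume_mm3",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D scalar array with a world affine (voxel center → mm, RAS+)."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 3:
            raise DimensionalityError(f"expected a 3-D volume, got {data.ndim}-D")
        if affine.shape != (4, 4):
            raise GeometryError(f"affine must be 4×4, got {affine.shape}")
        if not np.allclose(affine[3], [0.0, 0.0, 0.0, 1.0]):
            raise GeometryError("affine bottom row must be (0, 0, 0, 1)")
        det = np.linalg.det(affine[:3, :3])
        if not np.isfinite(det) or abs(det) <= 0.0:
            raise GeometryError("degenerate affine: 3×3 part is singular")
        edges = np.linalg.norm(affine[:3, :3], axis=0)
        if np.any(edges <= 0.0):
            raise GeometryError("voxel edge lengths must be strictly positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def same_geometry(self, other: "VolumeGrid", atol: float = 1e-4) -> bool:
        """True when shapes match and affines agree to within ``atol`` mm."""
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=atol)
        )

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel center, shape ``(*grid, 3)``."""
        ii, jj, kk = np.meshgrid(
            *(np.arange(n, dtype=float) for n in self.shape), indexing="ij"
        )
        vox = np.stack([ii, jj, kk], axis=-1)
        return vox @ self.affine[:3, :3].T + self.affine[:3, 3]


def _wrap_grid(grid: VolumeGrid) -> VolumeGrid:
    return grid


@dataclass(frozen=True)
class BinaryMask:
    """A :class:`VolumeGrid` whose values are exactly 0 or 1."""

    grid: VolumeGrid

    def __post_init__(self) -> None:
        vals = self.grid.data
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("binary mask values must be exactly 0 or 1")

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine

    @property
    def volume_mm3(self) -> float:
        return mask_volume_mm3(self)


@dataclass(frozen=True)
class LabelVolume:
    """A :class:`VolumeGrid` of non-negative integer labels; 0 is background."""

    grid: VolumeGrid

    def __post_init__(self) -> None:
        vals = self.grid.data
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.equal(np.mod(vals, 1), 0).all():
                raise ValueError("label volume values must be integers")
        if vals.min() < 0:
            raise ValueError("label volume values must be ≥ 0")

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine


@dataclass(frozen=True)
class ProbabilityVolume:
    """A :class:`VolumeGrid` of values in [0, 1]."""

    grid: VolumeGrid

    def __post_init__(self) -> None:
        vals = self.grid.data
        if vals.min() < 0.0 or vals.max() > 1.0:
            raise ValueError("probability volume values must lie in [0, 1]")

    @property
    def data(self) -> np.ndarray:
        return self.grid.data

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine


def read_volume(path: str | Path) -> VolumeGrid:
    """Read a NIfTI-1 file (optionally gzipped) into a RAS+ :class:`VolumeGrid`.

    Affine precedence follows the dominant convention: the sform is used when
    its code is positive, else the qform, else the pixdim-scaled fallback
    (this is what nibabel's ``img.affine`` implements); the choice is logged.
    Volumes stored in a non-RAS+ orientation are reoriented on read — data and
    affine jointly, so world geometry is unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(path)
    if img.ndim != 3:
        raise DimensionalityError(
            f"{path.name}: expected a 3-D image, got {img.ndim}-D"
        )
    sform_code = int(img.header["sform_code"])
    qform_code = int(img.header["qform_code"])
    source = "sform" if sform_code > 0 else ("qform" if qform_code > 0 else "base")
    log.debug("%s: affine taken from %s", path.name, source)
    img = nib.as_closest_canonical(img)
    data = np.asarray(img.dataobj)
    return VolumeGrid(data=data, affine=np.asarray(img.affine))


_ROLE_DTYPES = {
    BinaryMask: np.uint8,
    LabelVolume: np.int32,
    ProbabilityVolume: np.float32,
}


def write_volume(
    vol: VolumeGrid | BinaryMask | LabelVolume | ProbabilityVolume,
    path: str | Path,
) -> Path:
    """Write a volume as NIfTI-1 with the affine in both sform and qform.

    Binary masks are stored as unsigned 8-bit, label volumes as 32-bit
    integers, probability volumes as 32-bit float; a bare grid keeps its own
    dtype (floats narrowed to 32-bit). ``read_volume(write_volume(v))`` is the
    identity up to storage precision.
    """
    path = Path(path)
    dtype = None
    for role, dt in _ROLE_DTYPES.items():
        if isinstance(vol, role):
            dtype = dt
            break
    grid = vol if isinstance(vol, VolumeGrid) else vol.grid
    data = grid.data
    if dtype is None:
        dtype = np.float32 if np.issubdtype(data.dtype, np.floating) else data.dtype
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), grid.affine)
    img.header.set_sform(grid.affine, code=1)
    img.header.set_qform(grid.affine, code=1)
    nib.save(img, path)
    return path


def voxel_volume_mm3(vol: VolumeGrid | BinaryMask | LabelVolume | ProbabilityVolume) -> float:
    """Physical volume of one voxel: |det| of the affine's 3×3 part, in mm³."""
    grid = vol if isinstance(vol, VolumeGrid) else vol.grid
    return grid.voxel_volume_mm3


def mask_volume_mm3(mask: BinaryMask) -> float:
    """Foreground volume of a binary mask in mm³."""
    return float(np.count_nonzero(mask.data)) * voxel_volume_mm3(mask)
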