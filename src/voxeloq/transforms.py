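"""FLIRT affine conversion and resampling onto a template grid.

FSL's FLIRT expresses affines in "scaled-voxel" coordinates: voxel indices
multiplied by the voxel edge lengths, with an additional x-index flip
(i → n_x − 1 − i, in scaled units) for images whose voxel→world affine has a
positive determinant. Converting such a matrix M to a world→world transform
requires composing with each image's own voxel→world affine A and its
scaled-voxel map S:

    W = A_t · S_t⁻¹ · M · S_s · A_s⁻¹

Registration *estimation* is out of scope here: this module consumes matrices
produced by external registration tooling and guarantees their correct
application — historically the single most common source of silent
left/right errors in lesion mapping pipelines.

Masks and label volumes are always resampled with nearest-neighbour
interpolation (keeping them binary / label-valued without an arbitrary
re-binarization step); intensity images use trilinear.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._errors import GeometryError
from .grids import BinaryMask, VolumeGrid

__all__ = [
    "AffineTransform",
    "read_flirt_matrix",
    "write_world_matrix",
    "flirt_to_world_affine",
    "resample_to_grid",
    "to_template_space",
]


@dataclass(frozen=True)
class AffineTransform:
    """A 4×4 homogeneous map from source world mm to target world mm."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise GeometryError(f"transform must be 4×4, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise GeometryError("transform bottom row must be (0, 0, 0, 1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise GeometryError("transform 3×3 part is singular")
        object.__setattr__(self, "matrix", m)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        """Map an (n, 3) array of world points through the transform."""
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        return pts @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))


def read_flirt_matrix(path: str | Path) -> np.ndarray:
    """Read a FLIRT ``.mat`` file: four whitespace-separated rows of four."""
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise GeometryError(f"{path}: expected a 4×4 matrix, got {m.shape}")
    return m


def write_world_matrix(transform: AffineTransform, path: str | Path) -> Path:
    """Write a world-coordinate 4×4 as plain text (FLIRT-style layout)."""
    path = Path(path)
    np.savetxt(path, transform.matrix, fmt="%.10g")
    return path


def _fsl_scaled_voxel_map(geom: VolumeGrid) -> np.ndarray:
    """Voxel-index → FSL scaled-voxel affine for one image.

    Scaling by voxel edge lengths, composed with the x-index flip when the
    image's voxel→world affine has positive determinant (FSL's documented
    handedness convention).
    """
    edges = np.linalg.norm(geom.affine[:3, :3], axis=0)
    s = np.diag([edges[0], edges[1], edges[2], 1.0])
    if np.linalg.det(geom.affine[:3, :3]) > 0:
        flip = np.eye(4)
        flip[0, 0] = -1.0
        flip[0, 3] = geom.shape[0] - 1
        s = s @ flip
    return s


def flirt_to_world_affine(
    flirt_matrix: np.ndarray,
    source_geom: VolumeGrid,
    target_geom: VolumeGrid,
) -> AffineTransform:
    """Convert a FLIRT scaled-voxel matrix to a source-world → target-world map."""
    m = np.asarray(flirt_matrix, dtype=float)
    if m.shape != (4, 4):
        raise GeometryError(f"FLIRT matrix must be 4×4, got {m.shape}")
    if abs(np.linalg.det(m[:3, :3])) < 1e-12:
        raise GeometryError("FLIRT matrix is singular")
    a_s = source_geom.affine
    a_t = target_geom.affine
    s_s = _fsl_scaled_voxel_map(source_geom)
    s_t = _fsl_scaled_voxel_map(target_geom)
    w = a_t @ np.linalg.inv(s_t) @ m @ s_s @ np.linalg.inv(a_s)
    return AffineTransform(w)


_INTERP_ORDER = {"nearest": 0, "trilinear": 1}


def resample_to_grid(
    vol: VolumeGrid,
    transform: AffineTransform,
    target_geom: VolumeGrid,
    interpolation: str = "nearest",
) -> VolumeGrid:
    """Resample a volume onto ``target_geom`` under a world→world transform.

    Each output voxel center is mapped back through the inverse transform to
    a source location; out-of-field locations take 0.
    """
    if interpolation not in _INTERP_ORDER:
        raise ValueError(
            f"unknown interpolation {interpolation!r}; expected one of "
            f"{sorted(_INTERP_ORDER)}"
        )
    # output voxel -> target world -> (W^-1) source world -> source voxel
    full = (
        np.linalg.inv(vol.affine)
        @ np.linalg.inv(transform.matrix)
        @ target_geom.affine
    )
    out = ndimage.affine_transform(
        np.asarray(vol.data, dtype=float),
        matrix=full[:3, :3],
        offset=full[:3, 3],
        output_shape=target_geom.shape,
        order=_INTERP_ORDER[interpolation],
        mode="constant",
        cval=0.0,
        prefilter=False,
    )
    if interpolation == "nearest":
        out = out.astype(vol.data.dtype, copy=False)
    return VolumeGrid(data=out, affine=target_geom.affine)


def to_template_space(
    seg: BinaryMask,
    flirt_matrix: np.ndarray | None,
    anat_geom: VolumeGrid,
    template: VolumeGrid,
) -> BinaryMask:
    """Carry a binary segmentation onto the template grid.

    ``flirt_matrix`` is the FLIRT scaled-voxel matrix from the anatomical
    image (whose grid the segmentation shares) to the template; ``None``
    means the segmentation is already in template world coordinates and only
    a grid resampling is needed.
    """
    if seg.grid.shape != anat_geom.shape or not np.allclose(
        seg.affine, anat_geom.affine, atol=1e-4
    ):
        raise GeometryError("segmentation does not share the anatomical grid")
    if flirt_matrix is None:
        world = AffineTransform.identity()
    else:
        world = flirt_to_world_affine(flirt_matrix, anat_geom, template)
    out = resample_to_grid(seg.grid, world, template, interpolation="nearest")
    return BinaryMask(grid=VolumeGrid(out.data.astype(np.uint8), out.affine))
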