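"""NIfTI volume containers, affine-transform text I/O, and resampling.

Volumes are carried as lightweight dataclasses wrapping a numpy array plus a
4x4 world affine (voxel index -> mm, NIfTI RAS+ convention, 0-based indices).
Label volumes hold non-negative integer parcellation labels (0 = background);
scalar volumes hold finite real values. Affine transforms between named
spaces are read and written as whitespace-delimited 4-line text matrices (the
FLIRT ``.mat`` dialect: row-major, mapping source-space mm coordinates to
target-space mm coordinates).

Resampling is deliberately minimal: nearest-neighbor for labels (a label map
must never be averaged) and trilinear for continuous maps, both via
``scipy.ndimage.map_coordinates`` with zero fill outside the field of view.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "LabelVolume",
    "ScalarVolume",
    "AffineTransform",
    "read_label_volume",
    "write_label_volume",
    "read_scalar_volume",
    "write_scalar_volume",
    "read_affine",
    "write_affine",
    "resample_labels",
    "resample_scalar",
]


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got shape {affine.shape}")
    if abs(np.linalg.det(affine)) < 1e-12:
        raise ValueError("affine is singular")
    return affine


def voxel_sizes(affine: np.ndarray) -> tuple[float, float, float]:
    """Edge lengths in mm of one voxel along each index axis."""
    affine = np.asarray(affine, dtype=float)
    return tuple(float(np.linalg.norm(affine[:3, i])) for i in range(3))


@dataclass
class LabelVolume:
    """3-D integer-labeled lattice with a world affine.

    Houses gray matter parcellations (one positive label per region) and
    binary tissue masks. Labels must be non-negative integers; 0 is
    background.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"label volume must be 3-D, got {self.data.ndim}-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            bad = np.abs(self.data - rounded) > 1e-6
            if bad.any():
                val = self.data[bad].flat[0]
                raise ValueError(f"non-integer label value {val!r}")
            self.data = rounded.astype(np.int32)
        if self.data.size and self.data.min() < 0:
            raise ValueError(f"negative label value {self.data.min()}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return voxel_sizes(self.affine)

    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]


@dataclass
class ScalarVolume:
    """3-D finite-real-valued volume with a world affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"scalar volume must be 3-D, got {self.data.ndim}-D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("scalar volume contains non-finite values")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return voxel_sizes(self.affine)


@dataclass
class AffineTransform:
    """4x4 world-to-world transform between two named spaces."""

    matrix: np.ndarray
    source_space: str = "source"
    target_space: str = "target"

    def __post_init__(self) -> None:
        self.matrix = _check_affine(self.matrix)
        if not np.allclose(self.matrix[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("last affine row must be (0, 0, 0, 1)")

    @classmethod
    def identity(cls, source_space: str = "source", target_space: str = "target") -> "AffineTransform":
        return cls(np.eye(4), source_space, target_space)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Transform applying ``self`` first, then ``other``."""
        return AffineTransform(other.matrix @ self.matrix, self.source_space, other.target_space)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.target_space, self.source_space)


# ---------------------------------------------------------------------------
# file I/O


def read_label_volume(path: str | os.PathLike) -> LabelVolume:
    """Read a 3-D integer-labeled NIfTI image.

    Raises ``ValueError`` on 4-D input or voxel values that are not integers
    to within 1e-6.
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D label image, got {data.ndim}-D")
    return LabelVolume(data, img.affine)


def write_label_volume(vol: LabelVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.int32), vol.affine)
    nib.save(img, str(path))


def read_scalar_volume(path: str | os.PathLike) -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    data = np.squeeze(data) if data.ndim == 4 and data.shape[3] == 1 else data
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D image, got {data.ndim}-D")
    return ScalarVolume(data, img.affine)


def write_scalar_volume(vol: ScalarVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    nib.save(img, str(path))


def read_affine(path: str | os.PathLike, source_space: str = "source",
                target_space: str = "target") -> AffineTransform:
    """Read a 4-line whitespace-delimited 4x4 matrix (FLIRT .mat dialect)."""
    matrix = np.loadtxt(str(path))
    return AffineTransform(matrix, source_space, target_space)


def write_affine(xfm: AffineTransform, path: str | os.PathLike) -> None:
    np.savetxt(str(path), xfm.matrix, fmt="%.10g")


# ---------------------------------------------------------------------------
# resampling


def _source_coords(src_affine: np.ndarray, xfm: AffineTransform,
                   target_shape: tuple[int, int, int],
                   target_affine: np.ndarray) -> np.ndarray:
    """Voxel coordinates in the source grid for every target voxel.

    Chain: target index -> target mm -> (inverse world transform) source mm
    -> source index.
    """
    target_affine = _check_affine(target_affine)
    full = np.linalg.inv(src_affine) @ np.linalg.inv(xfm.matrix) @ target_affine
    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in target_shape), indexing="ij")
    ones = np.ones_like(ii)
    idx = np.stack([ii, jj, kk, ones]).reshape(4, -1)
    src = full @ idx
    return src[:3].reshape(3, *target_shape)


def resample_labels(vol: LabelVolume, xfm: AffineTransform,
                    target_shape: tuple[int, int, int],
                    target_affine: np.ndarray) -> LabelVolume:
    """Nearest-neighbor resampling of a label volume onto a target grid.

    Never invents labels; voxels mapping outside the source field of view
    become background (0).
    """
    coords = _source_coords(vol.affine, xfm, tuple(target_shape), target_affine)
    out = ndimage.map_coordinates(vol.data, coords, order=0, mode="grid-constant", cval=0)
    return LabelVolume(out.astype(vol.data.dtype), target_affine)


def resample_scalar(vol: ScalarVolume, xfm: AffineTransform,
                    target_shape: tuple[int, int, int],
                    target_affine: np.ndarray) -> ScalarVolume:
    """Trilinear resampling of a continuous volume onto a target grid."""
    coords = _source_coords(vol.affine, xfm, tuple(target_shape), target_affine)
    out = ndimage.map_coordinates(vol.data, coords, order=1, mode="grid-constant", cval=0.0)
    return ScalarVolume(out, target_affine)
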