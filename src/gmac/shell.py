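"""Gray-white matter transition shell construction.

The transition shell is the one-voxel-thick layer of white matter sitting
directly against gray matter: every white-matter voxel with at least one of
its six faces touching a gray matter region belongs to the shell. Each shell
voxel is then assigned to a single gray matter region by a face-voting rule —
the region owning the majority of the touching faces wins, and exact draws
are resolved by a uniform random choice among the tied regions, driven by a
recorded seed so runs are reproducible.

Contact is strictly face adjacency (6-connectivity); edge or corner contact
never counts.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .volume_io import LabelVolume

__all__ = [
    "TransitionShell",
    "unite_gray_mask",
    "face_neighbor_labels",
    "build_shell",
    "shell_to_label_volume",
    "shell_from_label_volume",
    "write_shell_table",
    "read_shell_table",
]

# the six face-neighbor offsets, fixed order
FACE_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
    dtype=int,
)


@dataclass
class TransitionShell:
    """Set of white-matter voxels at the gray-white boundary, each owned by
    one gray matter region.

    ``voxels`` is in lexicographic (i, j, k) order; ``roi_assignment`` maps
    each voxel triple to its positive region label; ``rng_seed`` is the seed
    that resolved any voting draws.
    """

    voxels: list[tuple[int, int, int]]
    roi_assignment: dict[tuple[int, int, int], int]
    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.voxels)) != len(self.voxels):
            raise ValueError("duplicate voxels in shell")
        self.affine = np.asarray(self.affine, dtype=float)

    def __len__(self) -> int:
        return len(self.voxels)

    def labels(self) -> np.ndarray:
        """Sorted region labels present in the shell."""
        return np.unique(np.fromiter(self.roi_assignment.values(), dtype=int))

    def voxels_of(self, roi: int) -> list[tuple[int, int, int]]:
        """Shell voxels assigned to one region, in lexicographic order."""
        return [v for v in self.voxels if self.roi_assignment[v] == roi]


def unite_gray_mask(parcellation: LabelVolume) -> LabelVolume:
    """Union of all gray matter regions as a binary mask."""
    if not (parcellation.data > 0).any():
        raise ValueError("no gray matter labels in parcellation")
    return LabelVolume((parcellation.data > 0).astype(np.int32), parcellation.affine)


def face_neighbor_labels(parcellation: LabelVolume, voxel: tuple[int, int, int]) -> Counter:
    """Multiset of gray labels on the up-to-6 face neighbors of ``voxel``.

    Neighbors outside the grid and background neighbors contribute nothing.
    """
    shape = parcellation.shape
    i, j, k = (int(c) for c in voxel)
    if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2]):
        raise ValueError(f"voxel {voxel} out of bounds for grid {shape}")
    counts: Counter = Counter()
    for di, dj, dk in FACE_OFFSETS:
        ni, nj, nk = i + di, j + dj, k + dk
        if 0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]:
            lab = int(parcellation.data[ni, nj, nk])
            if lab > 0:
                counts[lab] += 1
    return counts


def _neighbor_label_stack(labels: np.ndarray) -> np.ndarray:
    """(6, nx, ny, nz) array of face-neighbor labels, 0 beyond the grid."""
    stack = np.zeros((6,) + labels.shape, dtype=labels.dtype)
    for a, (di, dj, dk) in enumerate(FACE_OFFSETS):
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for ax, d in enumerate((di, dj, dk)):
            if d == 1:
                src[ax] = slice(1, None)
                dst[ax] = slice(0, -1)
            elif d == -1:
                src[ax] = slice(0, -1)
                dst[ax] = slice(1, None)
        stack[(a,) + tuple(dst)] = labels[tuple(src)]
    return stack


def build_shell(parcellation: LabelVolume, wm_mask: LabelVolume, seed: int = 0) -> TransitionShell:
    """Build the transition shell and vote each voxel's owning region.

    Both inputs must live on the same grid; gray labels and the white mask
    must not overlap (disjoint tissue classes). Ties in the face vote are
    broken uniformly at random among the tied labels using ``seed``; runs
    with the same seed are identical.
    """
    if parcellation.shape != wm_mask.shape or not np.allclose(parcellation.affine, wm_mask.affine):
        raise ValueError("grid mismatch between parcellation and white matter mask")
    wm = wm_mask.data > 0
    overlap = wm & (parcellation.data > 0)
    if overlap.any():
        vox = tuple(int(c) for c in np.argwhere(overlap)[0])
        raise ValueError(f"gray label and white mask overlap at voxel {vox}")

    neigh = _neighbor_label_stack(parcellation.data)  # (6, nx, ny, nz)
    has_gray = (neigh > 0).any(axis=0)
    in_shell = wm & has_gray
    shell_idx = np.argwhere(in_shell)  # lexicographic order

    rng = np.random.default_rng(seed)
    voxels: list[tuple[int, int, int]] = []
    assignment: dict[tuple[int, int, int], int] = {}
    for i, j, k in shell_idx:
        labs = neigh[:, i, j, k]
        labs = labs[labs > 0]
        values, counts = np.unique(labs, return_counts=True)
        tied = values[counts == counts.max()]
        lab = int(tied[0]) if len(tied) == 1 else int(rng.choice(tied))
        vox = (int(i), int(j), int(k))
        voxels.append(vox)
        assignment[vox] = lab
    return TransitionShell(voxels, assignment, parcellation.shape, parcellation.affine, rng_seed=seed)


def shell_to_label_volume(shell: TransitionShell) -> LabelVolume:
    """Serialize the shell as a label volume (region label on shell voxels)."""
    data = np.zeros(shell.grid_shape, dtype=np.int32)
    for vox, lab in shell.roi_assignment.items():
        data[vox] = lab
    return LabelVolume(data, shell.affine)


def shell_from_label_volume(vol: LabelVolume, rng_seed: int = 0) -> TransitionShell:
    """Rebuild a shell object from its serialized label volume."""
    idx = np.argwhere(vol.data > 0)
    voxels = [tuple(int(c) for c in v) for v in idx]
    assignment = {v: int(vol.data[v]) for v in voxels}
    return TransitionShell(voxels, assignment, vol.shape, vol.affine, rng_seed=rng_seed)


def write_shell_table(shell: TransitionShell, path: str | os.PathLike) -> None:
    """Write the shell as a 4-column text table with 0-based indices."""
    with open(path, "w") as fh:
        fh.write("# i j k label\n")
        for (i, j, k) in shell.voxels:
            fh.write(f"{i} {j} {k} {shell.roi_assignment[(i, j, k)]}\n")


def read_shell_table(path: str | os.PathLike, grid_shape: tuple[int, int, int],
                     affine: np.ndarray) -> TransitionShell:
    rows = np.loadtxt(path, dtype=int, comments="#", ndmin=2)
    voxels = [tuple(int(c) for c in r[:3]) for r in rows]
    assignment = {v: int(r[3]) for v, r in zip(voxels, rows)}
    return TransitionShell(voxels, assignment, tuple(grid_shape), affine)
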