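"""Simplified probabilistic streamline propagation on a direction field.

This module produces per-region streamline visitation-count volumes. It can
either ingest externally computed tractography count maps (one NIfTI volume
per seeded region) or generate them itself with a deliberately simple
propagator: a phantom supplies a principal fiber direction per voxel plus an
angular dispersion, and streamlines are integrated with a fixed step, a
curvature stopping rule, and an inclusion mask — the same control parameters
probabilistic tractography tools expose (5000 samples, curvature threshold
0.2, 200 steps of 0.5 mm, distance correction), which are the defaults here.

The propagator is a stand-in for full posterior-sampling tractography: it
models orientation uncertainty as isotropic Gaussian angular jitter around
one principal direction, which is exact on phantoms and makes every stage of
the downstream pipeline testable without diffusion MRI data.

Propagation rule: each step moves ``step_length_mm`` along the (jittered)
field direction at the current voxel. Fiber orientations are axes, not
vectors, so each candidate direction is first sign-aligned with the previous
step (flipped when their dot product is negative); the streamline then
terminates when the aligned cosine falls below ``curvature_threshold``, when
it would leave the inclusion mask, when it enters a voxel with no defined
direction, or after ``max_steps``. Bidirectional seeding launches one branch
along the field polarity at the seed and one against it.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass

import numpy as np

from .shell import TransitionShell
from .volume_io import ScalarVolume, read_scalar_volume, write_scalar_volume

__all__ = [
    "TrackingParams",
    "DirectionField",
    "VisitationMap",
    "propagate_streamline",
    "seed_roi_tracking",
    "track_all_rois",
    "load_visitation_maps",
    "write_visitation_map",
    "visitation_filename",
]


@dataclass
class TrackingParams:
    """Streamline propagation settings.

    ``n_samples`` streamlines are launched per seed voxel.
    ``curvature_threshold`` is the minimum cosine between successive step
    directions; ``step_length_mm`` the fixed step; ``dispersion_deg`` the
    standard deviation of the Gaussian angular jitter applied to the field
    direction at every step (0 = deterministic). With ``distance_correction``
    each voxel increment is weighted by the streamline's path length in mm at
    first visit; without it counts are integer visits.
    """

    n_samples: int = 5000
    curvature_threshold: float = 0.2
    max_steps: int = 200
    step_length_mm: float = 0.5
    distance_correction: bool = True
    dispersion_deg: float = 0.0
    bidirectional: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.step_length_mm <= 0:
            raise ValueError("step_length_mm must be positive")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        if not -1.0 <= self.curvature_threshold <= 1.0:
            raise ValueError("curvature_threshold must lie in [-1, 1]")
        if self.dispersion_deg < 0:
            raise ValueError("dispersion_deg must be non-negative")

    def to_config(self, path: str | os.PathLike) -> None:
        """Serialize as a flat key=value text file."""
        with open(path, "w") as fh:
            for key, val in asdict(self).items():
                fh.write(f"{key}={val}\n")

    @classmethod
    def from_config(cls, path: str | os.PathLike) -> "TrackingParams":
        kwargs: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                val = val.strip()
                if key in ("n_samples", "max_steps", "seed"):
                    kwargs[key] = int(val)
                elif key in ("distance_correction", "bidirectional"):
                    kwargs[key] = val.lower() in ("true", "1", "yes")
                else:
                    kwargs[key] = float(val)
        return cls(**kwargs)


@dataclass
class DirectionField:
    """Principal fiber direction per voxel plus an inclusion mask.

    ``vectors`` has shape (nx, ny, nz, 3); nonzero vectors must be unit
    length, the zero vector marks voxels with no defined direction.
    Streamlines must stay inside ``inclusion_mask``.
    """

    vectors: np.ndarray
    affine: np.ndarray
    inclusion_mask: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[3] != 3:
            raise ValueError("vectors must have shape (nx, ny, nz, 3)")
        norms = np.linalg.norm(self.vectors, axis=3)
        nonzero = norms > 0
        if nonzero.any() and np.abs(norms[nonzero] - 1.0).max() > 1e-6:
            raise ValueError("nonzero direction vectors must be unit length")
        self.affine = np.asarray(self.affine, dtype=float)
        self.inclusion_mask = np.asarray(self.inclusion_mask) > 0
        if self.inclusion_mask.shape != self.vectors.shape[:3]:
            raise ValueError("inclusion_mask shape does not match vector grid")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]


@dataclass
class VisitationMap:
    """Per-seed-region volume counting streamline visits at each voxel."""

    seed_roi: int
    counts: np.ndarray
    affine: np.ndarray
    params: TrackingParams | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.min() < 0:
            raise ValueError(f"negative count in visitation map for seed {self.seed_roi}")
        self.affine = np.asarray(self.affine, dtype=float)


def _mm_to_voxel(affine_inv: np.ndarray, pos: np.ndarray) -> tuple[int, int, int]:
    idx = affine_inv[:3, :3] @ pos + affine_inv[:3, 3]
    nearest = np.rint(idx).astype(int)
    return int(nearest[0]), int(nearest[1]), int(nearest[2])


def _inside(shape: tuple[int, int, int], vox: tuple[int, int, int]) -> bool:
    return all(0 <= c < n for c, n in zip(vox, shape))


def _jitter(direction: np.ndarray, dispersion_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate ``direction`` by a Gaussian-distributed polar angle about a
    uniformly random perpendicular axis."""
    if dispersion_rad == 0.0:
        return direction
    # orthonormal basis perpendicular to direction
    ref = np.array([1.0, 0.0, 0.0]) if abs(direction[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    theta = rng.normal(0.0, dispersion_rad)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    axis = np.cos(phi) * u + np.sin(phi) * v
    out = np.cos(theta) * direction + np.sin(theta) * axis
    return out / np.linalg.norm(out)


def propagate_streamline(
    fieldvol: DirectionField,
    start_mm: np.ndarray,
    params: TrackingParams,
    rng: np.random.Generator,
    initial_sign: float = 1.0,
) -> np.ndarray:
    """Integrate one streamline from ``start_mm``; returns (n_points, 3) mm
    positions including the start, with n_points <= max_steps + 1."""
    affine_inv = np.linalg.inv(fieldvol.affine)
    pos = np.asarray(start_mm, dtype=float)
    vox = _mm_to_voxel(affine_inv, pos)
    if not _inside(fieldvol.shape, vox) or not fieldvol.inclusion_mask[vox]:
        raise ValueError(f"streamline start {tuple(pos)} outside inclusion mask")
    path = [pos.copy()]
    prev_dir: np.ndarray | None = None
    dispersion_rad = np.deg2rad(params.dispersion_deg)
    for _ in range(params.max_steps):
        direction = fieldvol.vectors[vox]
        if not np.any(direction):
            break
        if prev_dir is None:
            direction = initial_sign * direction
        direction = _jitter(direction, dispersion_rad, rng)
        if prev_dir is not None:
            # orientations are axes: align sign with the previous step,
            # then gate on the aligned cosine
            cos = float(np.dot(prev_dir, direction))
            if cos < 0.0:
                direction = -direction
                cos = -cos
            if cos < params.curvature_threshold:
                break
        nxt = pos + params.step_length_mm * direction
        nvox = _mm_to_voxel(affine_inv, nxt)
        if not _inside(fieldvol.shape, nvox) or not fieldvol.inclusion_mask[nvox]:
            break
        pos = nxt
        vox = nvox
        prev_dir = direction
        path.append(pos.copy())
    return np.array(path)


def _accumulate(counts: np.ndarray, path_voxels: list[tuple[int, int, int]],
                arc_lengths: list[float], distance_correction: bool,
                weight: float = 1.0) -> None:
    """Each streamline increments each visited voxel once; with distance
    correction the increment is the path length in mm at first visit."""
    seen: dict[tuple[int, int, int], float] = {}
    for vox, arc in zip(path_voxels, arc_lengths):
        if vox not in seen:
            seen[vox] = arc
    for vox, arc in seen.items():
        counts[vox] += weight * (arc if distance_correction else 1.0)


def seed_roi_tracking(fieldvol: DirectionField, shell: TransitionShell, roi: int,
                      params: TrackingParams) -> VisitationMap:
    """Launch ``n_samples`` streamlines from every shell voxel of one region
    and count unique-voxel visits.

    Deterministic for a fixed ``params.seed``; the seed and region label
    together drive the per-streamline random stream.
    """
    seeds = shell.voxels_of(int(roi))
    if not seeds:
        raise ValueError(f"ROI {roi} absent from shell")
    affine = fieldvol.affine
    affine_inv = np.linalg.inv(affine)
    counts = np.zeros(fieldvol.shape, dtype=float)
    rng = np.random.default_rng([params.seed & 0x7FFFFFFF, int(roi)])
    signs = (1.0, -1.0) if params.bidirectional else (1.0,)
    # with zero dispersion every streamline from a given seed voxel is
    # identical, so propagate once and weight by n_samples
    deterministic = params.dispersion_deg == 0.0
    n_repeats = 1 if deterministic else params.n_samples
    weight = float(params.n_samples) if deterministic else 1.0
    for seed_vox in seeds:
        start_mm = affine[:3, :3] @ np.array(seed_vox, dtype=float) + affine[:3, 3]
        for _ in range(n_repeats):
            path_voxels: list[tuple[int, int, int]] = []
            arcs: list[float] = []
            for sign in signs:
                path = propagate_streamline(fieldvol, start_mm, params, rng, initial_sign=sign)
                for p_i, point in enumerate(path):
                    path_voxels.append(_mm_to_voxel(affine_inv, point))
                    arcs.append(p_i * params.step_length_mm)
            _accumulate(counts, path_voxels, arcs, params.distance_correction, weight)
    return VisitationMap(int(roi), counts, affine, params)


def track_all_rois(fieldvol: DirectionField, shell: TransitionShell,
                   params: TrackingParams) -> list[VisitationMap]:
    """Seed every region present in the shell independently."""
    return [seed_roi_tracking(fieldvol, shell, int(roi), params) for roi in shell.labels()]


def visitation_filename(roi: int) -> str:
    return f"seed_{int(roi)}_paths.nii.gz"


def write_visitation_map(vmap: VisitationMap, directory: str | os.PathLike) -> str:
    path = os.path.join(str(directory), visitation_filename(vmap.seed_roi))
    write_scalar_volume(ScalarVolume(vmap.counts, vmap.affine), path)
    return path


def write_direction_field(fieldvol: DirectionField, directory: str | os.PathLike) -> None:
    """Persist a field as vectors.nii.gz (4-D, last axis xyz) plus
    inclusion_mask.nii.gz."""
    import nibabel as nib
    directory = str(directory)
    nib.save(nib.Nifti1Image(fieldvol.vectors.astype(np.float32), fieldvol.affine),
             os.path.join(directory, "vectors.nii.gz"))
    nib.save(nib.Nifti1Image(fieldvol.inclusion_mask.astype(np.int16), fieldvol.affine),
             os.path.join(directory, "inclusion_mask.nii.gz"))


def read_direction_field(directory: str | os.PathLike) -> DirectionField:
    import nibabel as nib
    directory = str(directory)
    vec_img = nib.load(os.path.join(directory, "vectors.nii.gz"))
    mask_img = nib.load(os.path.join(directory, "inclusion_mask.nii.gz"))
    vectors = np.asanyarray(vec_img.dataobj, dtype=float)
    # re-normalize against float32 round-off so the unit-norm contract holds
    norms = np.linalg.norm(vectors, axis=3, keepdims=True)
    np.divide(vectors, norms, out=vectors, where=norms > 0)
    return DirectionField(vectors, vec_img.affine, np.asanyarray(mask_img.dataobj))


def load_visitation_maps(paths: list[str | os.PathLike],
                         roi_labels: list[int]) -> list[VisitationMap]:
    """Ingest externally computed count volumes, one per seed region.

    All volumes must share one grid; negative counts are rejected.
    """
    if len(paths) != len(roi_labels):
        raise ValueError(f"{len(paths)} paths but {len(roi_labels)} labels")
    maps: list[VisitationMap] = []
    ref: ScalarVolume | None = None
    for path, roi in zip(paths, roi_labels):
        vol = read_scalar_volume(path)
        if ref is None:
            ref = vol
        elif vol.shape != ref.shape or not np.allclose(vol.affine, ref.affine):
            raise ValueError(f"grid mismatch: {path}")
        if vol.data.min() < 0:
            raise ValueError(f"negative count in {path}")
        maps.append(VisitationMap(int(roi), vol.data, vol.affine))
    return maps
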