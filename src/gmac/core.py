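"""Gray matter axonal connectivity map (GMAC) computation.

A GMAC assigns each transition-shell voxel a measure of the axonal pathways
entering or exiting the adjacent gray matter. At a shell voxel owned by
region k the raw value f is the total number of streamlines traversing that
voxel when every *other* region is seeded — the voxel's own region is
excluded so that local seeding does not inflate the estimate of cortical
connectivity. The raw count is compressed as f' = log(f + 1) (natural log;
the base cancels in the normalization) and min-max scaled within subject,

    F = (f' - f'_min) / (f'_max - f'_min),

where f'_min and f'_max are the minimal and maximal nonzero log counts over
all shell voxels of that subject. Voxels with f = 0 carry F = 0 and are
flagged in a provenance mask, distinguishing "no measured connectivity" from
"minimum measured connectivity".
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .shell import TransitionShell, shell_to_label_volume
from .tracking import VisitationMap
from .volume_io import AffineTransform, ScalarVolume, resample_scalar, write_scalar_volume

__all__ = [
    "GMACVolume",
    "sum_nonlocal_counts",
    "log_transform",
    "normalize_within_subject",
    "compute_gmac",
    "gmac_to_standard_space",
    "write_gmac",
]


@dataclass
class GMACVolume:
    """Raw, log-transformed, and normalized connectivity on one shell.

    ``f`` is the adjacency-excluded streamline count, ``f_prime`` its
    log(f+1) transform, ``F`` the within-subject min-max normalized value in
    [0, 1] at voxels with nonzero counts. ``zero_mask`` flags shell voxels
    with f = 0 (no measured connectivity), which carry F = 0 by convention.
    """

    f: np.ndarray
    f_prime: np.ndarray
    F: np.ndarray
    f_prime_min: float
    f_prime_max: float
    zero_mask: np.ndarray
    shell_ref: TransitionShell
    affine: np.ndarray


def sum_nonlocal_counts(shell: TransitionShell, maps: list[VisitationMap]) -> ScalarVolume:
    """Adjacency-excluded streamline count per shell voxel.

    At a shell voxel assigned to region k, sums the counts of every
    visitation map whose seed region is not k; zero outside the shell.
    Requires one map per region present in the shell, all on the shell's
    grid.
    """
    by_roi = {m.seed_roi: m for m in maps}
    missing = [int(lab) for lab in shell.labels() if int(lab) not in by_roi]
    if missing:
        raise ValueError(f"missing visitation map for ROI label(s) {missing}")
    for m in maps:
        if m.counts.shape != shell.grid_shape or not np.allclose(m.affine, shell.affine):
            raise ValueError(f"grid mismatch for visitation map of ROI {m.seed_roi}")

    total = np.zeros(shell.grid_shape, dtype=float)
    for m in maps:
        total += m.counts
    f = np.zeros(shell.grid_shape, dtype=float)
    for vox in shell.voxels:
        own = shell.roi_assignment[vox]
        f[vox] = total[vox] - (by_roi[own].counts[vox] if own in by_roi else 0.0)
    return ScalarVolume(f, shell.affine)


def log_transform(f_vol: ScalarVolume) -> ScalarVolume:
    """Elementwise f' = log(f + 1), natural base."""
    if f_vol.data.min() < 0:
        raise ValueError(f"negative count {f_vol.data.min()} in raw connectivity volume")
    return ScalarVolume(np.log1p(f_vol.data), f_vol.affine)


def normalize_within_subject(f_prime_vol: ScalarVolume, shell: TransitionShell,
                             f_vol: ScalarVolume) -> GMACVolume:
    """Min-max scale the log counts over the subject's nonzero shell voxels.

    f'_min and f'_max are taken over shell voxels with f > 0 only; those
    voxels get F in [0, 1], voxels with f = 0 get F = 0 and are flagged in
    ``zero_mask``.
    """
    idx = tuple(np.array(shell.voxels).T) if shell.voxels else ((), (), ())
    f_shell = f_vol.data[idx]
    fp_shell = f_prime_vol.data[idx]
    nonzero = f_shell > 0
    if not nonzero.any():
        raise ValueError("no connectivity signal: all shell voxels have f = 0")
    fp_min = float(fp_shell[nonzero].min())
    fp_max = float(fp_shell[nonzero].max())
    if fp_max == fp_min:
        raise ValueError("degenerate normalization range: f'(max) = f'(min)")

    F = np.zeros(shell.grid_shape, dtype=float)
    vals = np.zeros(len(shell.voxels), dtype=float)
    vals[nonzero] = (fp_shell[nonzero] - fp_min) / (fp_max - fp_min)
    F[idx] = vals
    zero_mask = np.zeros(shell.grid_shape, dtype=bool)
    zm = np.zeros(len(shell.voxels), dtype=bool)
    zm[~nonzero] = True
    zero_mask[idx] = zm
    return GMACVolume(
        f=f_vol.data.copy(),
        f_prime=f_prime_vol.data.copy(),
        F=F,
        f_prime_min=fp_min,
        f_prime_max=fp_max,
        zero_mask=zero_mask,
        shell_ref=shell,
        affine=np.asarray(shell.affine, dtype=float),
    )


def compute_gmac(shell: TransitionShell, maps: list[VisitationMap]) -> GMACVolume:
    """Full chain: adjacency-excluded sum, log transform, normalization."""
    f_vol = sum_nonlocal_counts(shell, maps)
    fp_vol = log_transform(f_vol)
    return normalize_within_subject(fp_vol, shell, f_vol)


def gmac_to_standard_space(gmac: GMACVolume, xfm_to_t1: AffineTransform,
                           xfm_to_mni: AffineTransform,
                           target_shape: tuple[int, int, int],
                           target_affine: np.ndarray) -> ScalarVolume:
    """Move the normalized map to a standard grid via the composed affine.

    The two transforms (native diffusion -> T1, T1 -> standard) are composed
    and applied once with trilinear interpolation; output values are clamped
    to be non-negative.
    """
    composed = xfm_to_t1.compose(xfm_to_mni)
    out = resample_scalar(ScalarVolume(gmac.F, gmac.affine), composed,
                          tuple(target_shape), target_affine)
    return ScalarVolume(np.maximum(out.data, 0.0), out.affine)


def write_gmac(gmac: GMACVolume, out_dir: str | os.PathLike, subject: str = "subject") -> dict[str, str]:
    """Write raw f and normalized F volumes plus a key=value sidecar."""
    out_dir = str(out_dir)
    paths = {
        "raw": os.path.join(out_dir, f"{subject}_gmac_raw.nii.gz"),
        "gmac": os.path.join(out_dir, f"{subject}_gmac.nii.gz"),
        "sidecar": os.path.join(out_dir, f"{subject}_gmac.txt"),
    }
    write_scalar_volume(ScalarVolume(gmac.f, gmac.affine), paths["raw"])
    write_scalar_volume(ScalarVolume(gmac.F, gmac.affine), paths["gmac"])
    with open(paths["sidecar"], "w") as fh:
        fh.write(f"f_prime_min={gmac.f_prime_min!r}\n")
        fh.write(f"f_prime_max={gmac.f_prime_max!r}\n")
        fh.write(f"n_shell_voxels={len(gmac.shell_ref)}\n")
        fh.write(f"n_zero_voxels={int(gmac.zero_mask.sum())}\n")
        fh.write(f"shell_seed={gmac.shell_ref.rng_seed}\n")
    return paths
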