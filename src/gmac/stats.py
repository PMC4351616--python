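"""Voxel-based statistical analysis of connectivity maps across subjects.

The normalized maps live in one standard grid, so any voxelwise statistic
applies. Implemented here is the descriptive correlation analysis: Gaussian
smoothing (FWHM in mm, converted per axis to voxel units from the affine),
voxelwise Pearson correlation between the map value and a subject covariate,
Fisher z-transformation z = atanh(r) * sqrt(n - 3), and one-sided
z-thresholding. An optional Benjamini-Hochberg FDR correction over the
analysis mask is available for confirmatory use; the plain z cutoff mirrors
the descriptive display the method was introduced with.

Voxels where the map is constant across subjects (or outside the requested
minimum subject count) are excluded from the analysis mask and carry NaN in
the r and z maps — never a silent zero.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .volume_io import LabelVolume, ScalarVolume, voxel_sizes

__all__ = [
    "StatMap",
    "fwhm_to_sigma_mm",
    "smooth_volume",
    "voxelwise_correlation",
    "threshold_map",
    "fdr_threshold_map",
    "summary_table",
    "read_covariate_table",
]

_GAUSS = 2.0 * np.sqrt(2.0 * np.log(2.0))  # FWHM / sigma


def fwhm_to_sigma_mm(fwhm_mm: float) -> float:
    return fwhm_mm / _GAUSS


@dataclass
class StatMap:
    """Voxelwise correlation results: ``r``, Fisher ``z``, per-voxel subject
    count, and the analysis mask. Out-of-mask voxels hold NaN."""

    r: np.ndarray
    z: np.ndarray
    n_per_voxel: np.ndarray
    mask: np.ndarray
    affine: np.ndarray
    threshold: float | None = None


def smooth_volume(vol: ScalarVolume, fwhm_mm: float) -> ScalarVolume:
    """Gaussian smoothing with an isometric kernel of the given FWHM in mm.

    Sigma is converted to voxel units per axis from the affine; reflective
    boundaries keep the total image mass (no edge attenuation of shell
    signal).
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_mm = fwhm_to_sigma_mm(fwhm_mm)
    sigma_vox = [sigma_mm / vs for vs in voxel_sizes(vol.affine)]
    out = ndimage.gaussian_filter(vol.data, sigma=sigma_vox, mode="reflect")
    return ScalarVolume(out, vol.affine)


def voxelwise_correlation(maps: list[tuple[ScalarVolume, float]],
                          min_subjects: int | None = None) -> StatMap:
    """Pearson r and Fisher z per voxel between map value and covariate.

    All maps must share one grid. Voxels with zero variance across subjects
    are excluded from the mask; with fewer than ``min_subjects`` defined
    values (default: all subjects) likewise.
    """
    if len(maps) < 4:
        raise ValueError(f"need at least 4 subjects, got {len(maps)}")
    vols = [m[0] for m in maps]
    cov = np.array([m[1] for m in maps], dtype=float)
    if np.ptp(cov) == 0:
        raise ValueError("constant covariate")
    ref = vols[0]
    for v in vols[1:]:
        if v.shape != ref.shape or not np.allclose(v.affine, ref.affine):
            raise ValueError("grid mismatch across subject maps")
    n = len(maps)
    if min_subjects is None:
        min_subjects = n

    stack = np.stack([v.data for v in vols])  # (n, nx, ny, nz)
    defined = np.isfinite(stack)
    n_per_voxel = defined.sum(axis=0)
    # subjects enter a voxel only where defined; NaN-aware moments
    x = np.where(defined, stack, 0.0)
    c = np.where(defined, cov[:, None, None, None], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nv = n_per_voxel.astype(float)
        mean_x = x.sum(axis=0) / nv
        mean_c = c.sum(axis=0) / nv
        dx = np.where(defined, stack - mean_x, 0.0)
        dc = np.where(defined, cov[:, None, None, None] - mean_c, 0.0)
        sxx = (dx * dx).sum(axis=0)
        scc = (dc * dc).sum(axis=0)
        sxc = (dx * dc).sum(axis=0)
        r = sxc / np.sqrt(sxx * scc)

    mask = (n_per_voxel >= max(min_subjects, 4)) & (sxx > 0) & (scc > 0)
    r = np.where(mask, r, np.nan)
    # Fisher transform; r of exactly +/-1 is clipped to keep z finite
    r_c = np.clip(r, -1.0 + 1e-12, 1.0 - 1e-12)
    with np.errstate(invalid="ignore"):
        z = np.arctanh(r_c) * np.sqrt(np.maximum(n_per_voxel - 3, 0))
    z = np.where(mask, z, np.nan)
    return StatMap(r=r, z=z, n_per_voxel=n_per_voxel, mask=mask, affine=ref.affine)


def threshold_map(stat: StatMap, z_cut: float, direction: str = "less_than") -> LabelVolume:
    """Binary volume of in-mask voxels passing a one-sided z cutoff."""
    if direction not in ("less_than", "greater_than"):
        raise ValueError(f"unknown direction {direction!r}")
    with np.errstate(invalid="ignore"):
        passing = stat.z < z_cut if direction == "less_than" else stat.z > z_cut
    passing = passing & stat.mask
    return LabelVolume(passing.astype(np.int32), stat.affine)


def fdr_threshold_map(stat: StatMap, alpha: float = 0.05,
                      direction: str = "less_than") -> LabelVolume:
    """Benjamini-Hochberg FDR over the analysis mask, one-sided."""
    if direction not in ("less_than", "greater_than"):
        raise ValueError(f"unknown direction {direction!r}")
    z = stat.z[stat.mask]
    p = sps.norm.cdf(z) if direction == "less_than" else sps.norm.sf(z)
    m = len(p)
    passing_flat = np.zeros(m, dtype=bool)
    if m:
        order = np.argsort(p)
        thresh = alpha * (np.arange(1, m + 1)) / m
        below = p[order] <= thresh
        if below.any():
            k = np.max(np.nonzero(below)[0])
            passing_flat[order[: k + 1]] = True
    out = np.zeros(stat.z.shape, dtype=np.int32)
    out[stat.mask] = passing_flat
    return LabelVolume(out, stat.affine)


def summary_table(stat: StatMap, thresholded: LabelVolume) -> pd.DataFrame:
    """One-row summary: voxels passing, peak z, peak voxel coordinates."""
    n_pass = int(thresholded.data.sum())
    if stat.mask.any():
        # peak = most extreme |z| among in-mask voxels
        z_in = np.where(stat.mask, stat.z, np.nan)
        peak_flat = np.nanargmax(np.abs(z_in))
        peak = np.unravel_index(peak_flat, stat.z.shape)
        peak_z = float(stat.z[peak])
    else:
        peak, peak_z = (np.nan, np.nan, np.nan), np.nan
    return pd.DataFrame([
        {
            "n_voxels_passing": n_pass,
            "peak_z": peak_z,
            "peak_i": peak[0],
            "peak_j": peak[1],
            "peak_k": peak[2],
            "n_mask_voxels": int(stat.mask.sum()),
        }
    ])


def read_covariate_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a delimited table of subject id and covariate value.

    Expects two columns; the first is the subject id, the second the
    covariate. A header line is detected automatically.
    """
    with open(path) as fh:
        first = fh.readline()
    sep = next((d for d in ("\t", ",", ";") if d in first), r"\s+")
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.shape[1] < 2:
        raise ValueError("covariate table needs at least two columns")
    df = df.iloc[:, :2]
    df.columns = ["subject_id", "covariate"]
    df["covariate"] = pd.to_numeric(df["covariate"], errors="raise")
    return df
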