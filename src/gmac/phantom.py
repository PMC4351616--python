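"""Synthetic phantoms and cohorts for exercising the full pipeline.

Phantoms emulate the geometry the method operates on: compact gray matter
regions (balls) embedded in a white matter volume, connected by straight (or
one-elbow polyline) fiber bundles carrying a coherent direction field. The
direction field is the bundle's axis inside the bundle and zero elsewhere,
optionally contaminated with randomly oriented background voxels
(``noise_level``). Every output satisfies the input contracts of the shell,
tracking, and map-computation stages, so the pipeline can be validated end
to end without any imaging data.

Cohorts emulate a multi-subject study with a planted covariate effect: one
template connectivity map is computed from the phantom, and each subject's
map is the template plus a linear covariate effect at chosen shell voxels
plus Gaussian noise, clamped to [0, 1]. The default covariate is drawn
uniformly on (30, 51) years, matching a middle-aged adult cohort in mean and
spread. Planting on maps (rather than re-tracking each subject) keeps the
statistical stage's properties decoupled from tracking cost; a per-subject
re-tracking mode exists for end-to-end runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import GMACVolume, compute_gmac
from .shell import TransitionShell, build_shell
from .tracking import DirectionField, TrackingParams, track_all_rois
from .volume_io import LabelVolume, ScalarVolume

__all__ = [
    "BundleSpec",
    "PhantomSpec",
    "CohortSpec",
    "Phantom",
    "make_phantom",
    "template_gmac",
    "make_cohort",
]


@dataclass
class BundleSpec:
    """A fiber bundle between two regions: straight, or one elbow through
    ``waypoint_mm``. ``radius_mm`` sets the tube's half-width;
    ``dispersion_deg`` is the suggested tracking jitter for this bundle."""

    roi_a: int
    roi_b: int
    radius_mm: float = 1.2
    waypoint_mm: tuple[float, float, float] | None = None
    dispersion_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.roi_a == self.roi_b:
            raise ValueError("bundle endpoints must be distinct ROIs")


@dataclass
class PhantomSpec:
    """Geometry of a synthetic head: ``n_rois`` gray balls of radius
    ``roi_radius`` on a ring (or at explicit ``roi_centers``), white matter
    filling the rest of the brain box, and the listed bundles."""

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    n_rois: int = 2
    roi_radius: float = 3.0
    bundle_specs: list[BundleSpec] = field(default_factory=list)
    roi_centers: list[tuple[float, float, float]] | None = None
    noise_level: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 2:
            raise ValueError("need at least 2 ROIs")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")
        for b in self.bundle_specs:
            for roi in (b.roi_a, b.roi_b):
                if not 1 <= roi <= self.n_rois:
                    raise ValueError(f"bundle references missing ROI {roi}")


@dataclass
class CohortSpec:
    """Multi-subject study design with a planted linear covariate effect.

    ``slope`` is the change in normalized connectivity per covariate unit at
    each effect voxel; ``noise_sd`` the between-subject Gaussian noise on
    every shell voxel. ``effect_voxels=None`` plants the effect at every
    shell voxel where the template map is positive.
    """

    n_subjects: int = 18
    covariate_name: str = "age"
    covariate_range: tuple[float, float] = (30.0, 51.0)
    effect_voxels: list[tuple[int, int, int]] | None = None
    slope: float = -0.005
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.covariate_range
        if not hi > lo:
            raise ValueError("covariate_range must be increasing")


@dataclass
class Phantom:
    """A generated phantom: parcellation, white matter mask, direction
    field, plus per-bundle voxel masks for ground-truth checks."""

    parcellation: LabelVolume
    wm_mask: LabelVolume
    field: DirectionField
    bundle_masks: list[np.ndarray]
    spec: PhantomSpec

    def __iter__(self):
        return iter((self.parcellation, self.wm_mask, self.field))


def _auto_centers(spec: PhantomSpec) -> list[np.ndarray]:
    nx, ny, nz = spec.grid_shape
    cx, cy, cz = (nx - 1) // 2, (ny - 1) // 2, (nz - 1) // 2
    ring = min(nx, ny) / 2.0 - spec.roi_radius - 3.0
    if ring <= 0:
        raise ValueError("grid too small for the requested ROI radius")
    centers = []
    for i in range(spec.n_rois):
        ang = 2.0 * np.pi * i / spec.n_rois
        # integer voxel centers so thin bundles pass through voxel centers
        centers.append(np.round([cx + ring * np.cos(ang), cy + ring * np.sin(ang), cz]))
    return centers


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from each point to segment ab."""
    ab = b - a
    t = np.clip((points - a) @ ab / (ab @ ab), 0.0, 1.0)
    closest = a + t[:, None] * ab
    return np.linalg.norm(points - closest, axis=1)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the phantom volumes; deterministic for a fixed seed."""
    shape = tuple(spec.grid_shape)
    centers = ([np.asarray(c, dtype=float) for c in spec.roi_centers]
               if spec.roi_centers is not None else _auto_centers(spec))
    if len(centers) != spec.n_rois:
        raise ValueError("number of centers does not match n_rois")

    ii, jj, kk = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
    points = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)

    # gray balls; the 1-voxel grid border stays outside the brain
    parc = np.zeros(shape, dtype=np.int32)
    for lab, c in enumerate(centers, start=1):
        ball = (np.linalg.norm(points - c, axis=1) <= spec.roi_radius).reshape(shape)
        if (parc[ball] > 0).any():
            raise ValueError(f"ROI {lab} overlaps a previously placed ROI")
        if ball[0].any() or ball[-1].any() or ball[:, 0].any() or ball[:, -1].any() \
                or ball[:, :, 0].any() or ball[:, :, -1].any():
            raise ValueError(f"ROI {lab} touches the grid border; no white matter margin")
        parc[ball] = lab

    brain = np.zeros(shape, dtype=bool)
    brain[1:-1, 1:-1, 1:-1] = True
    wm = brain & (parc == 0)

    vectors = np.zeros(shape + (3,), dtype=float)
    bundle_masks: list[np.ndarray] = []
    for b in spec.bundle_specs:
        a_c, b_c = centers[b.roi_a - 1], centers[b.roi_b - 1]
        knots = [a_c] + ([np.asarray(b.waypoint_mm, dtype=float)] if b.waypoint_mm else []) + [b_c]
        bundle = np.zeros(shape, dtype=bool)
        for s_a, s_b in zip(knots[:-1], knots[1:]):
            seg = (_segment_distance(points, s_a, s_b) <= b.radius_mm).reshape(shape)
            seg &= wm
            direction = (s_b - s_a) / np.linalg.norm(s_b - s_a)
            vectors[seg] = direction
            bundle |= seg
        bundle_masks.append(bundle)

    if spec.noise_level > 0:
        rng = np.random.default_rng(spec.seed)
        free = wm & ~np.any(vectors != 0, axis=3)
        idx = np.argwhere(free)
        n_noise = int(round(spec.noise_level * len(idx)))
        if n_noise:
            chosen = idx[rng.choice(len(idx), size=n_noise, replace=False)]
            dirs = rng.normal(size=(n_noise, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            vectors[tuple(chosen.T)] = dirs

    affine = np.eye(4)
    return Phantom(
        parcellation=LabelVolume(parc, affine),
        wm_mask=LabelVolume(wm.astype(np.int32), affine),
        field=DirectionField(vectors, affine, brain),
        bundle_masks=bundle_masks,
        spec=spec,
    )


def default_template_spec(seed: int = 0) -> PhantomSpec:
    """Standard asymmetric template: three gray balls, two axis-aligned
    bundles of unequal length, so the normalization range is non-degenerate.
    """
    return PhantomSpec(
        grid_shape=(28, 28, 24),
        n_rois=3,
        roi_radius=3.0,
        roi_centers=[(5.0, 11.0, 11.0), (21.0, 11.0, 11.0), (5.0, 21.0, 11.0)],
        bundle_specs=[BundleSpec(1, 2, radius_mm=1.6), BundleSpec(1, 3, radius_mm=1.6)],
        seed=seed,
    )


def template_gmac(spec: PhantomSpec | None = None, params: TrackingParams | None = None
                  ) -> tuple[Phantom, TransitionShell, GMACVolume]:
    """Run the full pipeline once on a phantom to obtain a template map."""
    if spec is None:
        spec = default_template_spec()
    phantom = make_phantom(spec)
    shell = build_shell(phantom.parcellation, phantom.wm_mask, seed=spec.seed)
    if params is None:
        # desk-scale defaults: enough samples for a smooth template, jitter
        # so the visitation counts span a range of values
        params = TrackingParams(n_samples=50, dispersion_deg=15.0,
                                distance_correction=True, seed=spec.seed)
    maps = track_all_rois(phantom.field, shell, params)
    return phantom, shell, compute_gmac(shell, maps)


def make_cohort(template: PhantomSpec, cohort: CohortSpec,
                params: TrackingParams | None = None,
                per_subject_tracking: bool = False,
                ) -> list[tuple[str, ScalarVolume, float]]:
    """Generate (subject_id, normalized map, covariate) triples.

    Covariates are uniform on ``cohort.covariate_range``. Each subject's map
    is the template map plus ``slope * (covariate - range midpoint)`` at the
    effect voxels plus Gaussian noise at every shell voxel, clamped to
    [0, 1]. With ``per_subject_tracking`` the template is re-tracked per
    subject (small sample count) before planting, exercising the whole chain.
    """
    phantom, shell, gmac = template_gmac(template, params)
    shell_idx = tuple(np.array(shell.voxels).T)
    lo, hi = cohort.covariate_range
    mid = 0.5 * (lo + hi)
    rng = np.random.default_rng(cohort.seed)
    covariates = rng.uniform(lo, hi, size=cohort.n_subjects)

    if cohort.effect_voxels is None:
        effect_voxels = [v for v in shell.voxels if gmac.F[v] > 0]
    else:
        effect_voxels = [tuple(int(c) for c in v) for v in cohort.effect_voxels]
        shell_set = set(shell.voxels)
        bad = [v for v in effect_voxels if v not in shell_set]
        if bad:
            raise ValueError(f"effect voxels not on the template shell: {bad[:3]}")

    subjects: list[tuple[str, ScalarVolume, float]] = []
    for s, cov in enumerate(covariates):
        if per_subject_tracking:
            base_params = params or TrackingParams(n_samples=50, dispersion_deg=15.0,
                                                   distance_correction=True)
            sub_params = replace(base_params, seed=(cohort.seed + 1000 + s) & 0x7FFFFFFF)
            maps = track_all_rois(phantom.field, shell, sub_params)
            base_F = compute_gmac(shell, maps).F
        else:
            base_F = gmac.F
        data = base_F.copy()
        data[shell_idx] += rng.normal(0.0, cohort.noise_sd, size=len(shell.voxels))
        for v in effect_voxels:
            data[v] += cohort.slope * (cov - mid)
        np.clip(data, 0.0, 1.0, out=data)
        subjects.append((f"sub-{s + 1:02d}", ScalarVolume(data, gmac.affine), float(cov)))
    return subjects
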