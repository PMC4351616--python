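# Methods

## The measure

The package quantifies regional gray matter connectivity on the gray–white
matter **transition shell**: the set of white-matter voxels having face
contact (6-connectivity; edges and corners never count) with at least one
gray matter region of a labeled parcellation. Each shell voxel is owned by
one region, chosen by majority vote over the up-to-six touching faces; exact
ties are broken by a uniform random draw among the tied labels driven by a
recorded seed, so a build is fully reproducible and only genuinely tied
voxels can differ across seeds. Gray labels and the white mask must be
disjoint; overlap is rejected as an input error rather than resolved
silently.

At a shell voxel owned by region *k*, the raw connectivity *f* is the sum of
streamline visitation counts over every seed region other than *k*
(adjacency exclusion: a region's own streamlines would otherwise dominate
its shell). Because tractography is not directional, *f* conflates traffic
to and from the adjacent cortex, and by construction the measure carries no
pairwise (origin/target) information — it is a regional scalar, not a
connectome edge weight, and graph metrics cannot be derived from it.

Counts are compressed as *f*′ = ln(*f* + 1) and min–max scaled within
subject over the shell voxels with *f* > 0:

F = (f′ − f′_min) / (f′_max − f′_min).

Choices worth stating:

- **Log base.** Natural log. Any base changes f′_min/f′_max by the same
  factor, which cancels in the ratio; this invariance is tested.
- **"Nonzero" values.** f′ > 0 ⇔ f > 0; for integer counts this is f ≥ 1,
  and the same rule covers fractional distance-corrected counts.
- **Extent of the min/max.** Over shell voxels only — *f* is undefined off
  the shell, so "across the entire brain" means all shell voxels brain-wide.
- **Zero-count voxels.** They get F = 0 *and* a flag in a provenance mask
  (`zero_mask`). Min–max scaling necessarily sends the lowest measured voxel
  to F = 0 as well, so the flag — not the value — distinguishes "no measured
  connectivity" from "minimum measured connectivity". Support claims in the
  tests are therefore stated on the measured set (f > 0), never on F > 0.
- **Degenerate range.** If every measured voxel has the same count (which
  happens on perfectly symmetric phantoms), f′_max = f′_min and
  normalization refuses with an explicit error instead of emitting 0/0.

Maps are moved between spaces (native diffusion → T1 → standard) by
composing the two 4×4 affines and applying the composition once:
nearest-neighbor interpolation for label volumes, trilinear for continuous
maps, zero fill outside the field of view. Affine estimation itself is out
of scope; transforms are inputs in the 4-line text format registration tools
emit.

## The simplified tracker

The pipeline's contribution is downstream of tractography, so the built-in
tracker is intentionally minimal: a **principal-direction field** (one unit
vector per voxel, zero where undefined) with isotropic Gaussian angular
jitter standing in for full posterior sampling of fiber orientation. Its
parameters mirror the standard tool defaults: 5000 samples per seed voxel,
curvature threshold 0.2, 200 maximum steps, 0.5 mm step length, distance
correction on.

Propagation: from a seed voxel center, repeat up to `max_steps` times — look
up the field at the current voxel (nearest-voxel lookup); stop if it is
zero; rotate it by a Gaussian polar angle (`dispersion_deg`) about a uniform
random perpendicular axis; because fiber orientations are axes rather than
vectors, flip the result if its dot product with the previous step is
negative; stop if the aligned cosine is below the curvature threshold; take
a 0.5 mm step and stop if it leaves the inclusion mask. Bidirectional
seeding launches one branch along each field polarity at the seed. A
consequence of per-step sign alignment is that a field reversing polarity
mid-bundle does not terminate a streamline — only genuine geometric turns
sharper than arccos(0.2) ≈ 78° do.

Counting: each streamline increments each voxel it visits **once**
(unique-voxel visitation, so loops cannot inflate counts); with distance
correction the increment is the streamline's path length in mm at first
visit, otherwise 1. Whether the published sample count applies per seed
voxel or per region is ambiguous in the method's description; per seed voxel
(the named tool's convention) is implemented. With zero dispersion the
propagator is deterministic, and all streamlines from one seed voxel are
identical; the implementation computes that path once and weights it by the
sample count, which is exactly equivalent and keeps phantom runs fast.

## Phantoms and synthetic cohorts

`make_phantom` builds the geometry the method needs: gray matter balls
(default radius 3 voxels) in a white-matter-filled brain box with a 1-voxel
background margin, straight or one-elbow fiber bundles (tubes of configurable
radius around the segment between region centers) carrying the bundle axis
as field direction, and optionally a fraction of randomly oriented
background voxels (`noise_level`). All outputs satisfy the downstream input
contracts and are deterministic per seed.

The default template (`default_template_spec`) is deliberately asymmetric —
three regions, two bundles of unequal length (radius 1.6 mm) — because a
single symmetric bundle yields identical counts at every measured voxel and
hence a degenerate normalization range. Tracked with 50 samples per seed
voxel and 15° dispersion, it produces ~60 measured shell voxels whose F
values span (0, 1), a desk-scale stand-in for the value spread of real maps.

`make_cohort` emulates a multi-subject study: covariates uniform on
(30, 51) — matching a middle-aged cohort in mean (≈40.5) and spread — and
per-subject maps equal to the template plus `slope × (covariate − midpoint)`
at chosen effect voxels plus Gaussian noise (default sd 0.02) at every shell
voxel, clamped to [0, 1]. Effects are planted on maps rather than re-tracked
per subject, separating statistical-stage validation from tracking cost; a
`per_subject_tracking` mode re-tracks each subject at small sample counts
for end-to-end runs. What the phantoms do **not** emulate: MRI contrast and
scanner noise, fiber crossings and fanning, partial-volume effects at the
gray–white interface, segmentation error, and between-subject anatomical
variability. Passing phantom tests therefore validates the algorithmic
contracts, not robustness to real-data artifacts.

Clamping to [0, 1] truncates the noise at voxels whose template value is 0
or 1 — most of the shell — so the Gaussian error model, and with it the
nominal Fisher-z tail, holds only at voxels clear of the bounds. Calibration
checks accordingly use either unclamped simulated nulls or interior-valued
voxels.

## Statistical stage

Smoothing is Gaussian with σ = FWHM / (2√(2 ln 2)) per axis, converted to
voxel units from the affine (anisotropic voxels get anisotropic σ in voxel
space, isotropic in mm). Reflective boundary handling preserves total image
mass and avoids attenuating shell signal at the volume edge.

The voxelwise statistic is Pearson correlation across subjects with Fisher
z = atanh(r)·√(n − 3); the published analysis names only a correlation
display, so this standard choice is an interpretation, documented here.
Voxels with zero variance in map or covariate, or fewer than the required
subject count (minimum 4), are excluded from the analysis mask and carry NaN
— never a silent zero. |r| = 1 is clipped by 1e-12 before atanh so z stays
finite. Thresholding is one-sided at a chosen z cutoff (the descriptive
z < −1 display by default, with nesting across cutoffs guaranteed);
Benjamini–Hochberg FDR over the mask is available for confirmatory use. No
cluster-extent or permutation inference is implemented.

Calibration targets were fixed by a Monte-Carlo oracle run before the tests
were written: at n = 18 the one-sided null rate of z < −1 is 0.155 ± 0.010
against the nominal Φ(−1) = 0.1587 (tests allow ±0.04 over 1000 voxels), and
planted effects of −0.005/unit with noise sd 0.02 are detected at z < −1
with sensitivity ≈ 1.0 (tests require ≥ 0.9).

## Problem sizes and numerical conventions

Phantom grids are 24³–28³ voxels at 1 mm isotropic with 50–100 streamline
samples per seed voxel — chosen so the whole validation suite and the
acceptance run complete in about a minute while every assertion that matters
(oracle equality, forced counts, calibration) is exact or tightly bounded.
The published cohort-scale numbers (a ~220k-voxel shell from an 82-region
atlas at MRI resolution) require subject data that is not redistributable
and are not reproduced here.

Voxel indexing is 0-based; world coordinates follow the NIfTI index→mm
affine convention (RAS+). Nearest-voxel lookups round half to even
(`np.rint`); resampling uses `grid-constant` boundary handling so
coordinates within half a voxel of the grid edge resolve to the edge voxel
rather than to background. Seeds fan out to stages by fixed offsets in the
CLI so each stage is independently reproducible; library functions take
their seeds explicitly.

## Known limitations

- The tracker is a stand-in: single fiber direction per voxel, isotropic
  jitter, no posterior over crossing fibers; real probabilistic tractography
  will differ near complex white matter.
- The measure inherits tractography's biases: shell voxels over large
  coherent bundles score high, voxels over crossing-fiber regions score low,
  independent of true cortical connectivity.
- Distance-correction semantics (path length at first visit) are one
  reasonable reading of the tool option the method used; integer counts are
  the exactly-testable default.
- Min–max normalization ties F to the subject's own extremes; between-group
  comparisons of F assume comparable within-subject ranges.
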