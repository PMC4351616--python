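# gmac — gray matter axonal connectivity maps

`gmac` computes a voxel-based measure of the axonal pathways entering and
exiting gray matter. Instead of reducing diffusion-MRI tractography to a
region-by-region connectome matrix, it scores every voxel of the
**gray–white matter transition shell** — the one-voxel layer of white matter
in face contact with cortex — by the amount of streamline traffic it carries
from all *non-adjacent* regions. The result is a whole-brain, scale-free
connectivity image that plugs directly into ordinary voxel-based statistics
(smoothing, voxelwise correlation, z-thresholding), the same machinery used
for lesion-symptom mapping.

It is intended for neuroimaging researchers who already have a labeled gray
matter parcellation, a white matter mask, and per-region streamline
visitation count volumes from probabilistic tractography — or who want to
validate the pipeline end to end on built-in phantoms with a simplified
tracker.

## The method

1. **Transition shell.** Every white-matter voxel with at least one of its
   six faces touching a gray matter region joins the shell. Each shell voxel
   is assigned to one region by a face vote: the region owning the majority
   of touching faces wins; exact draws are resolved uniformly at random
   among the tied regions with a recorded seed.
2. **Seeding and counting.** Each region's shell segment is seeded
   independently (default 5000 streamlines per seed voxel, curvature
   threshold 0.2, 200 steps of 0.5 mm, distance correction on), yielding one
   visitation-count volume per region. At a shell voxel assigned to region
   *k*, the raw connectivity is

   *f* = Σ over all seed regions ≠ *k* of that region's count at the voxel,

   excluding the adjacent region so local seeding cannot inflate the score.
3. **Normalization.** Counts are compressed and scaled within subject:

   *f*′ = log(*f* + 1),  *F* = [*f*′ − *f*′(min)] / [*f*′(max) − *f*′(min)],

   where *f*′(min), *f*′(max) are the minimal and maximal nonzero log counts
   over the subject's shell. Voxels with *f* = 0 get *F* = 0 and are flagged
   in a provenance mask ("no measured connectivity" vs "minimum measured").
4. **Statistics.** Normalized maps in a common grid are smoothed with a
   Gaussian kernel (FWHM in mm), correlated voxelwise with a subject
   covariate (Pearson *r*, Fisher *z* = atanh *r* · √(n − 3)), and displayed
   at a one-sided z cutoff; Benjamini–Hochberg FDR is available.

A simplified probabilistic tracker (principal-direction field + Gaussian
angular jitter) and a phantom/cohort generator make every stage testable
without MRI data; see `docs/methods.md` for the model details and
limitations.

## Worked example

```sh
python examples/02_track_and_map.py
```

```
shell voxels:                402
voxels with measured signal: 60
raw count range (f):         4.5 .. 571.5
log range f'(min)..f'(max):  1.705 .. 6.350
normalized F range:          0.000 .. 1.000
zero-flagged shell voxels:   342
```

A three-region phantom with two fiber bundles is built, its shell extracted
(402 voxels), and each region's shell segment seeded with 50 streamlines per
voxel. Sixty shell voxels carry foreign streamline traffic; their
distance-corrected counts span 4.5–571.5, giving a log range of 1.705–6.350
that min–max scaling maps onto F ∈ [0, 1]. The 342 remaining shell voxels
carry no non-local streamlines and are zero-flagged. `examples/03_cohort_stats.py`
continues with an 18-subject synthetic cohort carrying a planted −0.005/year
age effect and recovers all 10 planted voxels at z < −1 (peak z ≈ −5.97).

## Command line

The same pipeline is scriptable from a shell; every subcommand writes a
provenance JSON next to its outputs:

```sh
gmac phantom --seed 1 --out work/phantom
gmac build-shell work/phantom/parcellation.nii.gz work/phantom/wm_mask.nii.gz \
    --seed 1 --out work/shell
gmac track work/phantom work/shell/shell.nii.gz --n-samples 50 --seed 1 --out work/tracks
gmac compute work/shell/shell.nii.gz work/tracks --subject sub-01 --out work/gmac
gmac stats work/gmac covariates.tsv --fwhm 8 --z-cut -1 --out work/stats
```

Volumes are NIfTI-1; affine transforms are 4-line whitespace-delimited text
matrices (the FLIRT `.mat` dialect, row-major, source-mm → target-mm);
shells also export as a 4-column `# i j k label` text table with 0-based
indices; covariates are delimited text (subject id, value).

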