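# Methods

This note documents the measurement model implemented by `fociquant`, the
synthetic data used to validate it, the numerical conventions chosen where
more than one was defensible, and the limits of what the validation shows.

## Input model and conventions

An `ImageStack3D` is an ordered set of nonnegative 3D intensity grids
sharing one shape, indexed `(z, y, x)` internally, with a physical
`VoxelSize` in nm. The default geometry, 64.5 × 64.5 × 150 nm, corresponds
to widefield acquisition with a 150 nm z-step. User-facing coordinates are
`(x, y, z)`; voxel indices are 0-based and refer to voxel centres, so a
fractional index is a sub-voxel position and a physical position is simply
the index times the edge length per axis. The centre-vs-corner choice
shifts all positions by half a voxel rigidly and therefore cancels in
every distance, volume and angle.

Probe coordinates are treated as 1-based inclusive (genome-browser display
convention): the span of a probe is `end − start + 1` bp, quoted in kb
rounded half-up.

TIFF I/O goes through `tifffile` as OME-TIFF with the voxel size stored in
the OME physical-size fields. Real-world TIFF metadata is unreliable, so a
voxel size supplied by the caller always overrides the file; a file with
no usable metadata and no override is an error, never a guess.

## Chromatic calibration

The aberration model is a single translation per channel pair — the
"apparent offset" of the moving channel relative to the reference. It is
estimated from a field of multi-colour fiducial beads: beads are detected
per channel as local maxima on a lightly smoothed copy, centroided with
the same clip-and-threshold machinery used for foci (so the calibration
exercises the measurement path it protects), and matched across channels
by mutual nearest neighbour within a 500 nm gate — far below the enforced
bead spacing and above plausible offsets, so gating is uncritical.
The offset is the mean matched displacement; the RMS residual after
removing the mean is reported as calibration quality. At least three
matched beads are required; collinear beads are acceptable because only a
translation is fitted. Unmatched (spurious) beads are excluded and do not
perturb the estimate.

Correction translates the entire moving channel by −offset with trilinear
interpolation, filling shifted-in border voxels with the channel's
background median to avoid artificial rims. An exactly zero offset is a
bit-for-bit no-op. A coordinate-level fast path subtracts the offset from
moving-channel centroids instead; it agrees with image-level correction to
within ~0.15 voxel per axis (about 10 nm laterally). The residual
disagreement comes from trilinear resampling, which blurs a spot slightly
and asymmetrically at fractional shifts — visible to the nearly uniform
post-clip centroid weighting — and is negligible against the pipeline's
~50 nm distance tolerance. No spatially varying (field-dependent) model is
fitted; that is a documented limitation, not an option.

## Focus segmentation and measurement

Each seeded focus is measured on a 20 × 20 pixel × 7 z-step crop centred
on the seed (even sizes put the seed at index `n // 2`); crops crossing
the stack boundary are rejected, restricting analysis to interior loci.

Segmentation on the crop:

1. **Clip.** Default mode saturates intensities above the *nearest-rank*
   96.5th percentile of the crop (rank ⌈0.965·N⌉ of the ascending sorted
   intensities) to that percentile value. The intent is hot-pixel
   suppression; an alternative reading — saturate above 96.5% of the crop
   maximum — is provided as `clip_mode="fraction_of_max"`. Percentile mode
   is the default because it adapts to the crop's intensity distribution
   and makes the operation exactly enumerable.
2. **Threshold.** The mask is every voxel with post-clip intensity **≥**
   90% of the post-clip maximum. The comparison is inclusive; with
   percentile clipping the post-clip maximum equals the clip value
   whenever any voxel was clipped, so the mask is "the top ~3.5% of
   voxels, plus everything within 90% of them".
3. **Connected component.** One 26-connected component is kept — by
   default the largest, ties broken by unweighted component-centroid
   proximity to the crop centre; a `nearest_center` policy is available.
4. **Centroid.** Post-clip intensity-weighted mean voxel position within
   the mask, mapped to the parent stack's physical frame. Because clipped
   weights span only [0.9·clip, clip], this is close to a binary centroid;
   a weighted estimator is kept as the default standard sub-voxel choice.
5. **Volume.** Masked voxel count × voxel volume, exact arithmetic: one
   default voxel is 624 037.5 nm³ = 6.240375 × 10⁻⁴ µm³.

**Degeneracy flags** stand in for the visual inspection a human would do
on per-locus QC images: a mask smaller than 5 voxels, covering more than
half the crop, or touching a *lateral* (x/y) crop face is flagged and
excluded from summaries (never silently dropped from the table). The
border rule deliberately exempts the two z faces: the crop's axial extent
(7 × 150 nm ≈ ±1.5 σ_z of a deconvolved widefield spot) is intentionally
tight, so a mask reaching the first or last plane is the norm of this
imaging regime — empirically every well-formed synthetic focus does — and
the resulting axial truncation is symmetric on average and contributes
only a few nm to distance error. An all-zero crop is an error; a constant
crop yields a flagged degenerate result rather than an exception.

Pair measurements report the Euclidean 3D inter-centroid distance (NaN
with flags if either side is degenerate), per-channel volumes, and the
Pearson correlation of the two channels' *raw* intensities — unclipped and
unthresholded, but after chromatic correction — over congruent 20 × 20 × 7
crops. The correlation region is anchored at the rounded midpoint of the
two seeds so a single congruent region covers both signals; zero variance
in either crop gives an undefined (flagged) result.

Probe-triple angles use the law of cosines on the three centroids, with
the cosine clamped to [−1, 1] against floating error; coincident vertex
and arm is an error. The Monte-Carlo null — the mean angle at the middle
of three points i.i.d. uniform in a unit cube — is 60° exactly (the three
angles of a triangle sum to 180° and the labels are exchangeable), which
`random_angle_baseline` reproduces within sampling error.

## Group statistics

Distance and volume tables are summarised as medians with interquartile
ranges (linear-interpolation quartiles, numpy's default type-7 — no
convention is canonical, this one is stated). Volume distributions are
reported as cumulative frequency at bin edges spaced by exactly one voxel
volume starting at 0, right-inclusive. Group differences use the
tie-corrected Kruskal–Wallis test (scipy) followed by Dunn's pairwise z
tests on mean ranks with tie correction, two-tailed, Bonferroni-adjusted
by default (Holm available), stars coded at p < 0.05 / 0.01 / 0.001 /
0.0001. Dunn's test is implemented in-package and cross-checked in the
test suite against an independent hand-rank oracle and an exact
permutation enumeration on small groups.

Recovery against synthetic truth reports bias (mean signed error), RMSE
and median absolute error of measured versus true distances, joined on
(stack, locus). When the same loci are re-measured on z-resampled stacks
(100/150/200 nm), the median per-locus spread (max − min) quantifies the
pipeline's z-step tolerance.

## The synthetic-scene generator

The generator emulates the regime the pipeline targets: deconvolved
stacks with compact bright foci on a low background.

* **Spot model**: anisotropic 3D Gaussian, σ_xy = 130 nm, σ_z = 300 nm by
  default — a stand-in for a deconvolved widefield PSF chosen so a focus
  covers ≥ ~98 voxels above threshold in a 20 × 20 × 7 crop (the regime
  the 96.5% clip rule presumes). Peak amplitude 200 counts.
* **Noise**: Poisson shot noise on the rendered signal plus Gaussian
  readout background (mean 5, sd 2 counts); deconvolved images carry
  little background, hence low defaults. All noise is switchable off for
  oracle-grade scenes.
* **Geometry**: pairs place one spot per channel at a drawn true
  separation (fixed or uniform [lo, hi] nm) in a uniformly random 3D
  direction; triples place a vertex spot in one channel and two flanking
  arms in the other, with independently drawn arm lengths and vertex
  angle. Loci are laid out on a jittered grid; infeasible packings raise
  rather than truncate.
* **Chromatic aberration**: channel 1 is rendered translated by a
  configurable offset; truth records the aberration-free positions plus
  the applied offset, so calibration is tested against an exact answer.
* **Seed points** emulate manual clicking: apparent positions rounded to
  voxels and jittered uniformly by up to ±2 voxels per axis, clamped so
  the crop fits.
* **Bead fields** render the same beads in both channels (the second
  translated by the offset to recover): small calibration beads as PSF
  Gaussians, 500 nm volume-validation beads as PSF-blurred spheres (erfc
  radial profile, z stretched by the PSF anisotropy). Bead spacing is at
  least four diameters *and* one crop width plus 2σ_xy — calibration
  slides are sparse, and two beads inside one sub-volume would corrupt
  each other's centroids.

Fixed seed implies bit-identical scenes, truth tables and seed points.

What the generator does **not** model: STED depletion physics, nuclear
texture or chromatin polymer structure, spatially varying aberration,
replication (doubled) signals, or a real deconvolution algorithm.
Consequently, passing the synthetic benchmarks shows the *estimators* are
correct and well-conditioned in this regime; it does not certify accuracy
on real nuclei, where background structure, anisotropic spot shapes and
human seed selection add error sources the simulation omits.

## Problem sizes used in validation

The distance-recovery benchmark uses 100 paired loci at separations
uniform on 300–1000 nm in a 21 × 640 × 640 stack (median absolute error
~15–25 nm across seeds, against a 53 nm tolerance bound). The
group-discrimination check simulates 50 loci per condition at 350 vs
700 nm and repeats over 20 seeds. The random-angle null uses 10⁴ triples
(Monte-Carlo SE ≈ 0.3°). These sizes make the full validation run in
about a minute on one CPU while keeping Monte-Carlo error small against
every tolerance tested.

## Known limitations

* Translation-only chromatic model; no field-dependent aberration.
* No spot-model fitting (Gaussian/ellipsoid): centroiding replaces it, so
  strongly elongated or merged signals are only caught by the degeneracy
  flags, not resolved.
* No automatic nucleus segmentation or cell-cycle filtering; seed tables
  are assumed curated (replicated signals excluded upstream).
* The original analysis's exact choices of centroid weighting, threshold
  strictness and component policy are not recoverable; both modes of each
  are shipped, with defaults as documented above.
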