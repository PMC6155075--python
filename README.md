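# fociquant

Quantification of 3D DNA-FISH signals for single-cell chromatin-organisation
studies: chromatic calibration against fiducial beads, intensity-threshold
foci segmentation, inter-centroid 3D distances, signal volumes, Pearson
colocalization, probe-triple angles, and the nonparametric group statistics
used to compare cell populations — plus a synthetic 3D-microscopy scene
generator with full ground truth, so every measurement stage can be
validated without real imaging data.

## Who this is for

Labs measuring the spatial organisation of genomic loci (for example a
self-interacting chromatin domain and its flanking regions) by
multi-colour 3D FISH on deconvolved widefield or STED z-stacks. Typical
questions: *how far apart are two probe signals in 3D?* — *how much volume
does the chromatin under a probe occupy (compaction)?* — *how strongly do
two probe signals overlap?* — *are three probes arranged linearly or
folded?*

## The measurement model

Stacks are multi-channel intensity grids with physical voxel geometry
(default 64.5 × 64.5 × 150 nm). Images are first chromatically corrected:
the apparent offset of one colour channel relative to another is the mean
centroid displacement of multi-colour fiducial beads (0.1 µm TetraSpeck-
style), matched across channels by mutual nearest neighbour, and the
moving channel is translated by −offset (trilinear interpolation).

Each candidate focus, marked by a seed point, is measured from a
20 × 20 pixel × 7 z-step sub-volume centred on the seed:

1. intensities above the nearest-rank 96.5th percentile of the crop are
   saturated to that value (suppressing hot pixels);
2. the mask is every voxel ≥ 90% of the post-clip maximum, keeping one
   26-connected component;
3. the **centroid** is the post-clip intensity-weighted mean voxel
   position in nm; the **volume** is the masked voxel count × voxel
   volume (one default voxel = 6.240375 × 10⁻⁴ µm³);
4. the **inter-centroid distance** between the two channels' foci is the
   Euclidean 3D distance of the centroids;
5. **colocalization** is the Pearson correlation of the raw (unclipped)
   intensities of congruent 20 × 20 × 7 crops from the two channels;
6. for probe triples, the **vertex angle** θ follows from the law of
   cosines, c² = a² + b² − 2ab·cos θ, on the three centroid-to-centroid
   arm lengths; the null for unstructured arrangements is the 60° mean
   angle of three i.i.d. uniform random points.

Group comparisons use medians with interquartile ranges, cumulative volume
distributions in single-voxel-volume bins, and the Kruskal–Wallis test
with Dunn's multiple comparisons (Bonferroni; stars at p < 0.05, 0.01,
0.001, 0.0001).

## Worked example

The all-in-one demo simulates a 25-locus two-channel scene with a known
chromatic offset, calibrates it away using a simulated bead field, measures
every signal pair and evaluates recovery against the generator's truth:

```sh
$ fociquant demo --out demo_out --seed 1
25 loci: bias 11.0 nm, rmse 52.9 nm, median |err| 12.0 nm
outputs in demo_out
```

The three numbers compare measured inter-centroid distances with the true
simulated separations: the mean signed error (bias, 11 nm — well under one
xy pixel), the root-mean-square error, and the median absolute error
(12 nm). `demo_out/measurements.csv` holds one row per locus:

```
stack_id,locus_id,distance_nm,pearson_r,volume_um3_ch0,volume_um3_ch1,...
scene,L0000,343.0648186596787,0.3734572645508591,0.07238835,0.0680200875,...
scene,L0001,837.9370506002988,-0.11344731903963917,0.0705162375,0.078628725,...
```

`distance_nm` is the 3D inter-centroid distance, `pearson_r` the raw-
intensity colocalization of the pair, and the `volume_um3_*` columns the
segmented signal volume in each channel. Flagged (degenerate) loci are kept
in the table but excluded from summaries. The same stages are available
individually as `fociquant simulate / calibrate / measure / stats /
recover`, and as library functions (`fociquant.run_pipeline`,
`fociquant.measure_pair`, ...).

## Documentation

`docs/methods.md` describes the measurement model, the synthetic-scene
generator and its assumptions, all tunable parameters with defaults, and
known limitations.
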