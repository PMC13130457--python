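# Methods

This note documents the models, estimators, parameter choices and known
limitations behind each pipeline, and what the synthetic generators do
and do not emulate.

## Conventions

Images are held as `(c, z, y, x)` arrays with user-supplied voxel
spacing `(dz, dy, dx)` in µm; TIFF metadata is never trusted for
spacing.  Coordinates are 0-based; the "central frame" of a stack is
z-index `floor(nz/2)` (for even depths, the upper of the two central
planes — a deterministic convention, since "central" is ambiguous
there).  Angles are measured counter-clockwise from the +x (column)
axis with y pointing up, reported modulo 180° (an orientation is a
direction without sense).  Bins and thresholds use half-open
conventions unless stated: angle bins are [0,30), [30,60), [60,90] with
90° closing the last bin; the DE fold-change boundary is inclusive and
the p-value boundary strict, reading the filter literally as
"|fold change| ≥ 1.5 and p < 0.05".

Connectivity is 8-neighbor in 2D and 26-neighbor in 3D throughout, so
object counts are reproducible across tools.

## Orientation pipeline

Stages: bilateral filter → fiber segmentation → Frangi enhancement →
Otsu segmentation within the fiber → per-object orientation → fold
against the fiber axis → bin.

* **Bilateral filter** (`sigma_spatial` = 2 px, `sigma_range` = 0.15 of
  the intensity range).  The range sigma is expressed relatively so one
  setting works across bit depths; the output is rescaled back, so a
  constant image is a fixed point.
* **Fiber axis**: morphological closing (radius 5 px), Otsu, largest
  8-connected component; the axis is the principal axis of that mask
  from second central moments, a single global angle per frame.  This
  presumes one straight fiber dominating the field, which is how the
  fixtures are built and how single-fiber frames are acquired; curved
  fibers would need a local orientation field (out of scope).
* **Frangi vesselness**, bright-ridge polarity, scales 1–4 px (step 1),
  maximum over scales, rescaled to a unit maximum.  The scales bracket
  the ~1.2–1.5 px tube radii of the fixtures and typical confocal
  mitochondria at ~0.1 µm/px sampling.
* **Mitochondria segmentation**: Otsu on the vesselness values inside
  the fiber mask eroded by 8 px (fiber-edge step responses would
  otherwise survive as spurious objects aligned with the fiber);
  8-connected components ≥ 10 px.
* **Object orientation**: second central moments.  In the pipeline the
  moments are weighted by the vesselness response, which recovers
  sub-pixel accuracy; unweighted binary moments carry an
  angle-dependent rasterization wobble of up to ~2° on rods of the
  fixture's aspect ratio, enough to leak a few percent across a bin
  edge when most mass sits near it.  Objects with eccentricity < 0.3
  are excluded from angle statistics (a near-round object has no
  meaningful axis); the cutoff is configurable and reported.
* **Reliability**: summaries from fewer than 20 objects are flagged
  unreliable; degenerate frames (blank, constant) yield an empty,
  unreliable summary rather than an error, so batch runs skip rather
  than crash.

In-plane anisotropic pixels are rejected: moment angles are distorted
by anisotropic sampling and silently wrong answers are worse than an
error.

## 3D volumes and shape metrics

The learned surface segmentation used interactively in commercial
tools is replaced by a classical, fully reproducible stand-in:
physically isotropic Gaussian smoothing (`smooth_sigma` = 0.7 in units
of the finest voxel dimension, scaled per axis by spacing so a coarse
z-step is not over-blurred), global Otsu, 26-connected components,
minimum size 8 voxels (single-voxel noise floor).  The measurement
contracts are segmentation-agnostic: any label map can be fed to
`object_volumes`.

Volume is voxel count × voxel volume; the distribution summary reports
the median (midpoint convention for even n) and the empirical CDF, and
conditions are compared with the two-sample two-sided KS test
(asymptotic p).  Both pooled-object and per-muscle aggregation are
possible downstream; the tables carry per-object rows precisely so the
aggregation unit remains the caller's choice.

**Perimeter / circularity.**  Circularity 4πA/P² is exquisitely
sensitive to the perimeter estimator: naive pixel-edge counting biases
a digitized disk to ~0.62, weighted boundary-step counting to ~0.92,
and 4-direction Crofton estimates bias squares to ~0.88.  The
implemented estimator extracts the 0.5 iso-contour of the Gaussian
smoothed mask (σ = 1 px) by marching squares and sums the polygon
length.  Measured on test shapes: disk (r = 50 px) circularity 0.99,
square 0.80 (ideal π/4 ≈ 0.785), 100×3 rod 0.09.  For objects only a
few pixels across the smoothing dominates and circularity can exceed
1; metrics are only meaningful for objects ≳ 8 px in diameter.

## Nuclear/cytoplasmic ratio

The cytoplasmic reference is one global mean per image (not per-nucleus
annuli): the readout is defined as nuclear mean relative to *the*
cytoplasmic intensity, and a single reference is robust to sparse
cytoplasm.  Nuclei come from Otsu on the (physically isotropically)
smoothed DAPI channel; nuclei touching the lateral image border are
excluded (partial volumes bias means).  The fiber region is the union
of the Otsu-thresholded signal channel and the nuclei (nuclei dimmer
than cytoplasm — ratios < 1 — would otherwise fall outside the fiber).
Cytoplasm is the fiber minus nuclei dilated by 2 voxels.  Before
measuring, each nucleus is eroded by one in-plane voxel: segmentation
can overshoot the true boundary by about a voxel, and boundary voxels
carry partial-volume signal; without the erosion the recovered ratio is
biased ~4–5% toward 1, with it the noiseless fixture is recovered to
three decimals.  Sub-synaptic nuclei exclusion is delegated to an
optional exclusion mask — endplate detection is a separate concern.

The muscle, not the nucleus, is the unit of analysis: ratios are
averaged per muscle and muscle means are normalized to the
control-group grand mean (control mean ≡ 1 exactly).  Mixed group
labels within one muscle are rejected.  Group statistics (ANOVA etc.)
are left to standard statistics packages on the muscle-level table.

## Endplate morphometry and turnover

The endplate mask comes from the summed old+new bungarotoxin channels
(smoothing + Otsu + size filter ≥ 30 voxels): the sum is
label-composition invariant, so the mask does not depend on how far
turnover has progressed.  Volume is voxel count × voxel volume;
fragmentation is the number of 26-connected components ≥ 10 voxels.

**Pixel dominance** is defined here (the underlying idea — assign each
endplate voxel to the stronger label — leaves the normalization and tie
handling open).  Each channel is normalized to its own 99th-percentile
intensity within the mask (percentile rather than maximum for
robustness to hot pixels; per-channel rather than joint so the readout
is invariant to acquisition gain differences between fluorophores), and
a voxel is new-dominant when normalized new exceeds normalized old by
more than `tie_delta` = 0.05, old-dominant in the mirror case, tie
otherwise.  The turnover readout is the new-dominant voxel fraction,
reported alongside old and tie fractions so the decomposition always
sums to 1.

A structural consequence of any per-channel scale normalization: the
voxels that *define* a channel's percentile normalize to 1.0 in that
channel, so when one label class is (nearly) absent, roughly 1% of
voxels cannot be assigned to the majority class and read as ties.  A
fully "all-old" endplate therefore reads as ~99% old / ~1% tie, never
100/0; the new-dominant fraction itself is unaffected (exactly 0).
The synthetic generator makes this explicit: for injected fractions
with both classes ≥ ~1.1% of the mask it produces exact dominance
counts with zero ties; at the extremes it carries the percentile
anchors in a dedicated ~1.1% tier of majority voxels that tie by
construction, keeping the new-dominant count exact.

## DEG classification

DE flag: |log2FC| ≥ log2(1.5) (boundary inclusive) and p < 0.05
(strict), on raw p-values — the filter is applied to upstream model
output as-is, with no multiple-testing correction of its own (an FDR
column, if provided upstream, can simply be passed as the p column).
With D/I/E the flags of the DEN/SH_IN/SH_DE contrasts, the partition
is: no flags → none; D only → AD_untouched; ¬D with knockdown effects →
AIN^In / AIN^De / AIN^InDe; D∧I only → AD^In± by sign agreement of
SH_IN with DEN; D∧E only → AD^De± likewise; all three → AD^InDe, the
inverse subtype when the two knockdown effects disagree in sign.
"Correlation" between effects is implemented as sign agreement of the
log2 fold changes — per gene only the signs are well-defined.  The
classification is a partition (exactly one class per gene), verified
against a brute-force truth-table oracle.

Zero fold change on a sign-determining contrast is defensively mapped
to class `none` with a flag — unreachable in practice, since a flagged
contrast requires |log2FC| ≥ log2(1.5) > 0.

Z-score heatmap input: per gene, (x − row mean)/row SD across the three
contrasts, population-SD convention; constant rows are zeroed and
flagged rather than dropped.

## Synthetic generators

All generators are pure functions of their arguments including the
seed (one `numpy` `default_rng` per call), and all ground truth is
exact by construction — stratified largest-remainder counts for angle
bins and class counts, voxelized (not continuous) volumes, pre-noise
injected ratios, engineered dominance counts.

* **Fiber frames**: one straight fiber rendered as a rotated rectangle
  (half-width 16% of the frame side) whose ends are cut perpendicular
  to its axis, so the mask's principal axis equals the nominal fiber
  angle to < 0.05° — an image-clipped infinite band would bias the
  moment axis several degrees toward the frame diagonal.  Rods
  (default length 20–28 px, radius 1.2–1.5 px) are placed without
  overlap (3 px clearance, bounded retries, capacity error on
  failure), rendered by distance-to-segment thresholding with 1-px
  Gaussian edge softening, at intensities background 10 / fiber 60 /
  rod peak 200 so Otsu separates fiber from surround and vesselness
  separates rods from fiber.  Per-bin angle counts are exact; within a
  bin, relative angles are uniform, with a random side of the fiber
  axis.  Additive Gaussian noise, default σ = 5 (≈ 8% of the fiber
  level) — acquisition noise is not characterized in typical reports,
  so this is a package default, documented and adjustable.
* **Blob volumes**: non-touching ellipsoids (axis ratios 0.75–1.35,
  ≥ 2-voxel gaps so 26-connectivity never merges them), volumes drawn
  from a named family (`fixed`, `uniform`, `lognormal`); the recorded
  truth is each rasterized voxel count × voxel volume.  Volumes below
  8 voxels are rejected.
* **Nucleus/cytoplasm stacks**: a fiber cylinder along x; disjoint
  ellipsoidal nuclei away from borders; DAPI bright only in nuclei;
  signal exactly `ratio × cyto_level` in nuclei and `cyto_level` in
  the fiber before noise.
* **Endplates**: disjoint blob fragments as a stylized stand-in for
  the pretzel-shaped postsynaptic membrane; channel intensities as
  described under pixel dominance.
* **DE tables**: per requested class, fold changes with a ≥ 0.1
  log2-margin beyond the threshold on DE contrasts and strictly
  sub-threshold magnitude or super-threshold p on non-DE contrasts, so
  classification is margin-robust.

What the generators do **not** emulate: point-spread functions, photon
(Poisson) noise, uneven illumination, curved or multiple fibers,
touching mitochondria, EM texture, or RNA-seq count distributions
(only DE summary triples).  Passing recovery tests therefore
demonstrates correctness of the estimators under controlled geometry
and additive noise, not robustness to every acquisition artifact of
real microscopy.

## Problem sizes and defaults

The reproduction script runs 1000 rods per condition (frame side
≈ 1900 px) — enough that the three-point recovery band is dominated by
estimator behavior rather than counting noise — and completes in well
under a minute per condition on one CPU.  Unit and recovery tests use
60–500 objects per fixture, 15–20 nuclei per muscle, masks of ~10⁴
voxels and DE tables of 10–60 genes; KS power is checked at n = 500
per group over 100 seeded repetitions.

The two orientation condition presets encode the reported innervated
and 3-week-denervated 60–90° proportions (88.5% and 18.7%).  Only the
60–90° share is reported for the denervated condition; the split of
the remaining mass between 0–30° and 30–60° (0.580 / 0.233) is a
package choice reflecting a predominantly longitudinal network.

## Known limitations

* Single global fiber axis; no local orientation fields or curvature.
* The 3D segmentation stand-in is threshold-based; heavily overlapping
  or dim mitochondria will merge or vanish where a learned model might
  separate them.
* Circularity is undefined in practice below ~8 px object diameter.
* Pixel dominance at extreme turnover carries the structural ~1% tie
  floor described above.
* The DEG module consumes (log2FC, p) summaries; it neither fits DE
  models nor corrects for multiple testing.
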