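# Methods

## The measurement problem

Triple immunofluorescence marks neuronal nuclei (NeuN), astrocytes (GFAP)
and microglia (IBA1) in hippocampal sections.  ROIs of 600 × 400 µm are
acquired at 1024 × 1024 px in three z-layers 5 µm apart.  Wanted per ROI:
cell densities per class in cells/mm², the density of neuronal debris
(sub-somatic NeuN fragments being cleared inside astrocytic territory — an
apoptosis marker), and the thickness of the stratum pyramidale (its thinning
indexes neurodegeneration).  The central difficulty is that a single
z-plane cuts a soma in an arbitrary chord, so per-plane counting both
over-counts (one soma appears in several planes) and mis-sizes cells;
the pipeline therefore reasons across layers.

## Detection pipeline and its assumptions

1. **Gaussian blur** (σ = 0.6 µm) suppresses shot-like noise.  σ is
   physical and converted per axis: pixels are anisotropic
   (0.586 µm in x, 0.391 µm in y at the default calibration).
2. **Adaptive threshold**: pixel is foreground iff it exceeds the mean of
   its 30 µm neighbourhood by 6 intensity units.  This makes segmentation
   exactly invariant to any additive background field varying slower than
   the block size, which is why a planar illumination gradient (that
   defeats every global threshold) is harmless.  A Gaussian-weighted local
   mean is available by configuration.
3. **Opening then closing** with a 0.8 µm disk.  The open–close composition
   is an idempotent morphological filter; re-application is a no-op, which
   the tests assert.
4. **Blob measurement**: 8-connected components; area = pixel count × pixel
   area; Feret diameter = maximum pairwise distance between boundary-pixel
   centres with per-axis µm scaling (computed via the convex hull, equal to
   the O(n²) pairwise maximum).  Components touching the raster border are
   excluded by default — edge scatter and truncated somata are not
   measurable.
5. **Cross-layer linking**: blob A (layer i) may link to blob B (layer i+1)
   when |A∩B| / min(|A|,|B|) ≥ 0.60.  The smaller-area denominator is
   deliberate: a soma's cross-section shrinks away from its equator, and
   the smaller section being mostly contained in the larger one is the
   geometrically meaningful criterion.  Links are taken greedily,
   largest pixel overlap first, ties broken by centroid distance, then by
   enumeration order; each blob gets at most one predecessor and one
   successor.  On every random scene with ≤ 20 blobs/layer the greedy
   result equals an exhaustive reference matcher (tested).
6. **Cell rule**: a track is a cell iff it spans ≥ 2 consecutive layers and
   its largest Feret diameter **strictly** exceeds 6.5 µm.  Cells are
   counted per track, never per blob.
7. **Debris rule**: a NeuN blob with Feret in the closed interval
   [2.5, 6.5] µm that belongs to no cell track is accepted as debris when
   ≥ 50 % of its surrounding ring (blob dilated by 1 µm, minus the blob) is
   covered by the GFAP mask of the same layer.  Candidates sharing one
   (non-cell) track collapse to a single particle so a fragment segmented
   in two layers is never counted twice.

### Parameter defaults

| parameter | default | role |
|---|---|---|
| blur_sigma_um | 0.6 | noise suppression before thresholding |
| thresh_block_um | 30 | adaptive-threshold neighbourhood |
| thresh_offset | 6 | intensity margin over the local mean |
| morph_radius_um | 0.8 | speckle removal / gap closing |
| min_overlap_frac | 0.60 | cross-layer link criterion |
| min_cell_diag_um | 6.5 | strict cell size threshold |
| debris_diag_um | [2.5, 6.5] | closed debris size window |
| encircle_frac / ring_width_um | 0.5 / 1.0 | "encircled by GFAP" operationalisation |
| min_layer_support | 2 | minimum linked span for a cell |

The classification constants (60 %, 6.5 µm, 2.5–6.5 µm, ≥ 2 layers) are the
method's definition.  The preprocessing values are calibration choices: blur
σ and threshold offset were fixed by a bead-style calibration — disks of
known diameter (2.5–15 µm) were rendered at the default photometry and the
settings chosen to make the measured Feret diameter unbiased
(+0.00 µm mean error, ±0.2 µm spread at σ = 0.6 µm / offset = 6; the
combination σ = 1.0 µm / offset = 5 leaves a +0.2 µm median bias).
Unbiasedness matters because the debris upper bound coincides with the cell
lower bound: any systematic size error leaks fragments across the 6.5 µm
boundary in one direction.  All parameters are echoed into every result
file.

Encirclement (ring coverage ≥ 0.5 over a 1 µm ring) is a quantitative
stand-in for the qualitative "encircled by astrocytic signal" criterion;
both knobs are exposed.  Whether morphology is always applied or only on
visual inspection of clustering is exposed as `apply_morphology`
(default: always).

## Morphometry

Density is the exact ratio count / ROI area (mm²); `QuantResult` guarantees
density × area = count.  ROI tiling assigns objects by centroid, so tile
counts partition the total exactly.

Stratum pyramidale thickness is measured on the maximum-intensity NeuN
projection (one thickness per ROI).  The band row is anchored at the peak
of the column-averaged smoothed profile — an isolated bright soma cannot
hijack a column.  Per column the band extent is the contiguous run through
the band row above baseline + 0.5 × (peak − baseline); the baseline is
re-estimated in a second pass from the rows flanking the first-pass run,
which tracks local background gradients (a whole-column percentile
over-reaches by ~1 µm under a 10-unit planar gradient).  Columns with peak
contrast below 5 units carry no band; if more than half the columns are
bandless the result is flagged and the mean undefined.  The estimator is
invariant to intensity scaling and horizontal translation, and recovers a
noiseless synthetic 60 µm band within 2 px.  Non-horizontal bands are
handled by a user-supplied rotation angle; a hand-drawn band polygon can be
supplied instead (`thickness_from_polygon` = polygon area / axis extent).

## Method agreement

`bland_altman` reports bias (mean of algorithm − reference), precision (SD
of differences, ddof = 1), limits of agreement bias ± 1.96·SD, relative
bias as percentage of the grand mean of pairwise means, and a two-sided
test of the regression slope of differences on means (α = 0.05) as the
operationalisation of "no tendency of the difference to increase with the
mean".  Interchangeable ⇔ |percent bias| < 10 ∧ no trend.  With constant
differences the trend test is vacuous and reported as no-trend.  The
reference series is manual counting, optionally the element-wise mean of
two observers.  Note an agreement design needs spread in the measurand: if
the reference is constant across ROIs, difference and mean are collinear
and the trend test fires spuriously (the acceptance script therefore varies
true counts across its comparison scenes).

## Study bookkeeping

* Brain-to-plasma ratio = brain (ng/g) / plasma (ng/mL) per animal; absent
  brain samples yield an undefined ratio.  Summaries report the **mean of
  per-animal ratios** (not the ratio of means — these differ) with
  SEM = sample SD/√n; ratios enter summaries at full precision and are
  rounded only for display.  A compatibility flag (`as_sd`) reproduces the
  convention of tables that print the SD in the SEM row.  The bundled
  reference table carries measured cannabidiol concentrations at 1 h (Cmax)
  and 24 h (Cmin) after a 60 mg/kg oral dose, five rats per timepoint, one
  24 h brain sample excluded for inadequate perfusion.  Two of that table's
  printed summary cells are internally inconsistent (the 1 h brain mean
  does not equal the mean of its per-animal values; the 24 h ratio
  dispersion follows no consistent convention) and are not reproduced.
* Discrimination index DI = (TN − TF)/(TN + TF) ∈ [−1, 1]; the trial is
  invalid unless both familiarization interactions reached 2.5 s.
* Kindling: modified Racine scores 0–5; an animal is kindled at the second
  of the first two consecutive injections scoring ≥ 4; two consecutive
  stage-5 seizures on the first two doses exclude the animal at entry.
  Group summaries tabulate mortality fractions, injections-to-kindled,
  per-injection generalized-seizure counts, and latency/duration
  mean ± SEM.  Inferential statistics (log-rank, Mann–Whitney, ANOVA,
  mixed-effects) are delegated to standard packages and not re-implemented.

## Synthetic scenes: what they emulate, what they do not

The generator renders calibrated 3-channel stacks: NeuN somata as spheres
sampled by the z-planes (per-layer disk radius from chord geometry, so the
overlap rule is exercised on genuinely shrinking concentric
cross-sections); sphere depths are sampled so every soma is countable by
construction (nearest-plane chord > 7.4 µm, two planes cut).  Astrocytes
are somata with 4–6 straight radiating processes, microglia smaller somata
with shorter processes, each spanning two layers.  Debris fragments
(2.5–6.5 µm, single layer) receive a GFAP annulus at 0.8 arc coverage;
decoy fragments receive none.  An optional pyramidal band is rendered as a
confluent stripe — somata in the real stratum pyramidale are packed beyond
single-cell resolution, and the thickness estimator reads the band
envelope, not individual cells.  Background = offset 20 + planar gradient
of amplitude 10 in a random direction + additive Gaussian noise (SD 4);
optional Poisson shot noise is off by default.  Object amplitude is 15 over
background, chosen once so that the adaptive threshold cuts object profiles
near half-maximum (the regime where measured sizes track drawn sizes);
these photometric values are generator properties, not microscope facts.
Ground truth (object lists, band polygon, per-channel masks) is recorded
before noise.  Identical spec + seed is bit-identical.

Not emulated: PSF convolution, spectral bleed-through, refractive
aberration, touching somata outside the band, microglial activation
morphology, and real staining variability.  Passing recovery tests
therefore demonstrates the algorithm's logic (linking, sizing,
encirclement, invariances) under controlled geometry and photometry — not
performance on real tissue, which the Bland–Altman module is there to
validate against manual counts.

## Numerical conventions and degenerate inputs

Pixel coordinates are 0-based, origin top-left, (row, col); rectangles are
half-open in µm; µm→px edge conversion rounds to the nearest pixel (crop
composition is exact for grid-aligned rectangles).  Channel identity is by
explicit mapping (metadata, sidecar or argument), never by intensity
heuristics; reading a file without calibration raises instead of guessing.
RGB composites are unmixed by inverting the display-colour matrix
(green = NeuN, cyan = GFAP, red = IBA1), which is linearly invertible, so
split/merge round-trips.  Empty masks, empty scenes and bandless
projections are well-defined (zero counts / flagged results, never
exceptions); over-crowded scene specifications raise `PlacementError`.
Z-geometry ambiguity (step vs extent of a "5 µm, 3 layers, 10 µm deep"
acquisition) is left to reporting: the stack stores z-step and layer count.

## Problem sizes

Default test and acceptance scenes are the full 1024 × 1024 px, 3-layer,
3-channel ROI; unit tests use a reduced 300 × 200 µm scene.  The acceptance
script runs 10 fixed-count scenes for recovery, 10 varying-count scenes for
agreement, and one noiseless band scene; the whole script completes in
about half a minute on one CPU.
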