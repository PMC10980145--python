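# Methods

## The measurement model

The pipeline quantifies bright, roughly elliptical amyloid-β deposits in
a calibrated single-channel fluorescence micrograph. Its core assumptions
are:

* objects are brighter than their local neighborhood (so a local-mean
  threshold finds them regardless of slow background variation);
* objects are spatially separated at the analysis resolution (touching
  deposits are counted as one; there is no watershed splitting);
* the pixel size (μm/pixel) is known — every μm-valued output is
  conditional on it, and it must come from TIFF metadata or be supplied
  explicitly;
* the region of interest is a simple polygon drawn to exclude section
  edges and artifacts, and its *geometric* (shoelace) area — not a pixel
  count — is the density denominator, making densities
  resolution-independent.

Per-slide processing is strictly ordered: adaptive threshold →
morphological opening → ROI restriction → labeling → minimum-area filter
→ morphometry → classification → density. Objects clipped by the ROI
boundary are retained and measured as clipped, because masking happens
before labeling.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `window_px` | 51 | px | local-mean neighborhood side (odd). Must exceed the widest expected object in pixels, otherwise the object interior approaches its own window mean and falls below threshold ("hollowing"). At 0.25 μm/px, plaques reach ~80 px, so analyses at that scale use 129. |
| `offset` | 6.0 | intensity | added to the local mean; foreground requires `value > mean + offset` (strict). Set ≈ 2× the background noise SD: with Gaussian noise this leaves ~2% of background pixels as isolated specks, which the opening and area filter remove. |
| `opening_radius_px` | 1 | px | disk radius of the binary opening. Radius 1 (a 5-pixel cross) removes isolated noise pixels; it also erases genuine objects narrower than ~3 px, which bounds the resolvable object size from below. |
| `connectivity` | 8 | — | pixel adjacency for labeling (8 keeps diagonally contiguous deposit edges together). |
| `min_object_area_um2` | 0.5 | μm² | discards sub-resolution survivors after labeling. |
| `class_cutoff_diameter_um` | 6.0 | μm | equivalent-diameter split between oligomer-like and plaque-like objects — the geometric neighborhood between the ~2 μm and ~14 μm populations; ties go to plaque. |

"Diameter" throughout is the equivalent-area diameter `2√(A/π)`, the
standard morphometric convention when a single diameter is reported for
an irregular object.

Eccentricity uses the second-central-moment ellipse with the +1/12
unit-square correction on the diagonal moments. This matches the
convention of the classical region-properties implementations, makes a
single pixel exactly circular (e = 0), and keeps one-pixel-wide lines
finite. For objects more than ~10 px across it differs negligibly from
the uncorrected moments (the scikit-image `regionprops` values are used
as an independent cross-check in the tests).

The unpaired *t*-test is the classical pooled-variance Student test
(two-sided, df = nₐ + n_b − 2); Welch's unequal-variance form is
available via `equal_var=False`. Two identical constant groups return
t = 0, p = 1 by convention; zero pooled variance with unequal means is an
error. Per-image "adjust the threshold until the background disappears"
style intensity ranking is deliberately replaced by a *fixed*
user-supplied threshold per comparison batch
(`threshold_pixel_count`): the subjective per-image adjustment is not
reproducible in batch mode.

Regional summaries report both object-pooled statistics (headline
columns: every object of every slide pooled) and mean-of-slide-means
variants (`area_slide_mean`, `ecc_slide_mean`), because the two pooling
rules answer different questions and either may be wanted for comparison
with published tables. Sample SDs use the n−1 denominator and are
reported as missing when only one slide (or fewer than two objects)
contributes.

## The synthetic-data generator

`generate_micrograph` emulates the statistical structure the analysis
assumes — not the optics of a microscope. A frame contains a rectangular
"tissue" region (fraction `tissue_fraction` of the frame, default 0.9)
at `background_level` (default 20) on dark glass (level 0), with additive
Gaussian noise (SD 3) clipped at zero. Objects are flat-top ellipses at
`object_peak_intensity` (default 120, i.e. ~33 noise SDs above the
tissue level — a bright, well-stained preparation) whose pixel footprint
is exactly the set of pixel centers inside the ellipse, the same rule
`rasterize_truth` uses, so analytic area checks hold to a
perimeter-proportional pixelization bound.

Population defaults are the study conditions: oligomer equivalent
diameters 2.0 ± 0.3 μm, plaque diameters 14 ± 2 μm, eccentricities
0.5 ± 0.1, truncated at mean ± 3 SD (and ≥ 0.5 μm). The two-sided
truncation keeps the configured means exact and bounds each class's
support, so any cutoff strictly between the supports separates the
classes perfectly. Semi-axes follow from diameter and eccentricity as
`a = (d/2)/(1−e²)^¼`, `b = (d/2)(1−e²)^¼`, making the planted
equivalent diameter exactly `d`.

Placement is rejection sampling with a conservative bounding-circle test:
centers are drawn uniformly until every pair of objects keeps
`min_gap_px` (default 5 px) clearance and each ellipse lies entirely
inside the analysis ROI; exceeding `max_placement_attempts` raises an
error naming the crowding problem. The returned ROI is the tissue
rectangle inset by `roi_margin_px` (default 80 px): the glass→tissue
intensity step depresses a local mean up to half a window inside the
tissue, and the inset — the in-silico analogue of drawing ROIs away from
section edges — keeps that edge band out of the analysis. Keep
`roi_margin_px` ≥ `window_px / 2`.

What the generator does **not** emulate: uneven illumination,
object-internal intensity structure (plaque cores/halos), out-of-focus
light, touching or overlapping deposits, second channels, and non-convex
tissue boundaries. Passing recovery tests therefore demonstrate the
correctness of the measurement chain under the stated model, not
segmentation robustness on real tissue, where threshold and opening
parameters must be tuned per preparation.

## Problem sizes in the tests and the acceptance script

Recovery runs use 512×512 frames at 0.25 μm/px with 50 oligomers + 10
plaques per slide over 20 seeds: 0.25 μm/px gives the 2-μm class an
~8-px diameter, the smallest sampling at which its diameter and
eccentricity are measured without gross pixelization bias. The
four-region density cohort uses 0.5 μm/px at 768–1024 px so the ROI
reaches ~0.08–0.2 mm² and the planted published densities (170.90,
122.44, 89.72, 38.87 per mm²) map to distinct integer object counts. At
0.5 μm/px the smallest oligomers (≈1.1 μm, 2 px) can be erased by the
radius-1 opening, so recovered densities sit a few percent below the
planted values; the regional ordering is unaffected.

## Numerical choices

* The adaptive threshold compares `value · w² > (window sum) + offset · w²`
  using exact separable box sums, so the strict inequality behaves
  exactly on constant and integer-valued images (no pre-divided means,
  no floating drift).
* Opening treats out-of-frame pixels as foreground during erosion and
  background during dilation: a region flush with the frame edge is not
  eroded from outside, and the opening remains anti-extensive and
  idempotent.
* Component labels are renumbered 1..n in raster order of each
  component's first pixel, making label images reproducible across
  library versions.
* Pixel-in-polygon membership is boundary-inclusive, evaluated with exact
  geometric predicates on pixel centers at integer coordinates (0-based,
  row/col).
* Written TIFFs carry the pixel size twice: exactly (JSON image
  description) and as standard resolution tags (px/cm); reading prefers
  the exact value. Intensities are stored as float64 and round-trip
  bit-identically; integer TIFFs are read without rescaling.
* All simulator randomness flows through one `numpy` Generator seeded
  from the configuration; pipeline runs derive per-slide seeds from the
  run seed via `SeedSequence`, so outputs are bit-identical across
  reruns.

## Known limitations

* No watershed separation: deposits closer than the pixel grid resolves
  merge into one object.
* The tissue mask and the ROI are conflated in batch mode (the ROI is
  the tissue-bounding polygon); there is no automatic tissue detection.
* Densities depend on every segmentation parameter; cross-study
  comparisons require identical settings, which the run log records.
* The 2-μm class needs pixel sizes ≤ 0.25 μm/px for unbiased
  morphometry; at coarser sampling counts remain usable but per-object
  shape statistics degrade.
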