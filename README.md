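# abquant

Quantification of amyloid-β burden in single-channel fluorescence
micrographs of brain sections.

In mouse models of Alzheimer's disease (such as 5XFAD), fluorescently
labeled probes stain two morphologically distinct amyloid-β populations:
small soluble-oligomer-associated puncta (~2 μm imaged footprint) and
large insoluble plaques (~14–20 μm). `abquant` turns such micrographs into
per-object morphometry and regional summary statistics:

1. **Adaptive local thresholding** — a pixel is foreground iff its
   intensity exceeds the mean of its `window_px × window_px` neighborhood
   (mirror-padded) plus an `offset`, which suppresses slowly varying
   background while keeping bright objects of any absolute intensity.
2. **Morphological opening** with a discrete disk, removing noise specks
   smaller than the structuring element.
3. **ROI restriction** — analysis is limited to a drawn polygon (avoiding
   section edges and histological artifacts); the polygon's geometric
   area is the density denominator.
4. **Connected-component labeling** and a minimum-area filter.
5. **Morphometry** per object: area `A` (μm²), equivalent diameter
   `d = 2√(A/π)`, centroid, and eccentricity
   `e = √(1 − λ₂/λ₁)` from the eigenvalues λ₁ ≥ λ₂ of the second
   central moment matrix of the pixel coordinates (each pixel treated as
   a unit square: +1/12 on the diagonal moments).
6. **Classification** — oligomer-like if `d < cutoff` (default 6 μm,
   between the two populations), else plaque-like.
7. **Density and aggregation** — objects/mm² per slide
   (`count / ROI area`), then Table-style regional summaries
   (mean ± sample SD across slides, pooled object statistics, per-class
   diameters) and unpaired two-sample *t*-tests between cohorts.

Because real stained sections ship with no ground truth, the package
includes a **synthetic-micrograph generator** that plants non-overlapping
bright ellipses from configurable diameter/eccentricity populations on a
noisy tissue background and exports exact ground truth, so every stage of
the pipeline is verifiable end to end.

## Worked example

```python
from abquant import SlideAnalyzer
from abquant.simulate import SimulationConfig, generate_micrograph
import numpy as np

cfg = SimulationConfig(n_oligomers=50, n_plaques=10, pixel_size_um=0.25, seed=1)
image, truth, roi = generate_micrograph(cfg)
analyzer = SlideAnalyzer(window_px=129).fit(image, roi=roi)

print(f"objects found: {analyzer.n_objects_} (planted: {len(truth)})")
d = analyzer.density_
print(f"density: {d.density_per_mm2:.1f} objects/mm^2 over {d.roi_area_mm2:.4f} mm^2")
for cls in ("oligomer", "plaque"):
    diam = [m.equivalent_diameter_um for m in analyzer.objects_ if m.object_class == cls]
    print(f"{cls}: n={len(diam)}, mean equivalent diameter {np.mean(diam):.2f} um")
ecc = [m.eccentricity for m in analyzer.objects_]
print(f"mean eccentricity: {np.mean(ecc):.2f}")
```

prints

```
objects found: 60 (planted: 60)
density: 9104.1 objects/mm^2 over 0.0066 mm^2
oligomer: n=50, mean equivalent diameter 1.97 um
plaque: n=10, mean equivalent diameter 14.45 um
mean eccentricity: 0.50
```

Every planted object is recovered; the per-class mean diameters and the
mean eccentricity reproduce the configured populations (2 μm, 14 μm,
eccentricity 0.5); the density is exactly the count divided by the ROI
area. Note `window_px=129`: a local-mean threshold window must be wider
than the widest object (here plaques reach 80 px at 0.25 μm/px), or large
objects hollow out.

`SlideAnalyzer` is a scikit-learn-style estimator (`get_params`,
`set_params`, fitted attributes `mask_`, `labels_`, `objects_`,
`density_`); the individual stages are available both as transformers
(`AdaptiveThresholder`, `MorphologicalOpener`, `RoiRestrictor`,
`ObjectLabeler`) and as plain functions (`adaptive_threshold`,
`morphological_open`, `apply_roi`, `label_objects`).

## Command line

```sh
abquant simulate --config sim.yaml --out data/       # TIFFs + ground truth + ROIs
abquant quantify --config run.yaml --out results/    # morphometry + summary CSVs
abquant summarize --slides results/slides.csv \
    --morphometry results/morphometry.csv --out summary.csv
abquant compare --group-a a.csv --group-b b.csv      # unpaired t-test
```

Configurations are YAML; every effective parameter (including defaults)
is echoed into `run.log`, and a rerun with the same config and seed
reproduces all outputs bit-identically.

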