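# neurocollin

Curvature-corrected orientation and collinearity analysis of pyramidal
neurons from segmentation label masks.

## The problem

Hippocampal pyramidal neurons form a curved cell-body layer (the stratum
pyramidale) in which healthy somata point roughly perpendicular to the
layer. How uniformly they do so — their *collinearity* — differs between
subregions (CA1–CA3, subiculum, their uncal counterparts) and is a
candidate cytoarchitectonic marker. Measuring it at scale means
post-processing hundreds of thousands of instance segmentations: cleaning
false positives, extracting an axial orientation per soma, removing the
effect of layer curvature, and comparing subregions without
pseudoreplicating cases and sections.

`neurocollin` implements that post-segmentation pipeline. It consumes an
integer label mask from any external segmenter (e.g. Cellpose, invoked
through an optional adapter or loaded from file) plus the section image,
partition polygons and a manually drawn layer centerline, and produces
per-neuron orientation records, subregion collinearity summaries and
mixed-model group comparisons. A ground-truthed synthetic scene generator
makes every stage testable without tissue data.

## The measures

For each kept soma, an ellipse with the object's second image moments
gives the **uncorrected orientation** UncO ∈ [0°, 180°) (major axis vs
the x-axis, axial). With CorrA the direction from the soma centroid to
the nearest point on the layer centerline, the **corrected orientation**

    CoO = (CorrA − UncO + 90°) mod 180°

equals 90° exactly when the soma is perpendicular to the local layer,
independent of where on the curve it sits. Per subregion:

* **dev** — mean angular deviation: mean axial distance of the CoOs from
  90°, in degrees (0 = perfectly collinear);
* **var** — circular variance 1 − R̄ of the angle-doubled CoOs, in
  [0, 1] (axial data have period 180°, so angles are doubled before
  vector averaging).

Group comparison: neuron-level deviations are quantile-normalized per
slide (rank-based inverse normal, z = Φ⁻¹(r/(n+1))), modeled with a
linear mixed model (subregion fixed; case and slide random intercepts,
crossed), tested with a likelihood-ratio test, and all pairwise
subregion contrasts are Tukey-adjusted (single-step, joint multivariate
normal of the contrast statistics).

## Worked example

```python
from neurocollin import (ArcCurve, SceneSpec, generate_scene,
                         analyze_scene, mean_angular_deviation,
                         circular_variance)

# a curved lamina of 150 somata, axial von Mises noise kappa=8
scene = generate_scene(SceneSpec(
    curve=ArcCurve(center=(0, 0), radius=500, span_deg=(10, 170)),
    n_neurons=150, kappa=8.0, seed=11))

records, filt = analyze_scene(scene.image, scene.mask, scene.centerline)
coo = records["coo_deg"].dropna()
unco = records["unco_deg"].dropna()
print(f"dev(UncO) = {mean_angular_deviation(unco):.1f} deg")
print(f"dev(CoO)  = {mean_angular_deviation(coo):.1f} deg")
print(f"var(CoO)  = {circular_variance(coo):.3f}")
```

prints

```
dev(UncO) = 39.9 deg
dev(CoO)  = 8.4 deg
var(CoO)  = 0.067
```

The uncorrected deviation is huge because the layer itself curves
through ~160°; after curvature correction the deviation collapses to the
planted angular noise (an axial von Mises sample at κ = 8 has mean
absolute deviation ≈ 8.3°). On a noise-free scene dev(CoO) drops to
≈ 0.3° — rasterization error only.

The `examples/` directory walks through each capability (scene
simulation, false-positive filtering, curvature correction, rose/line
plots, mixed-model subregion comparison); each script prints the numbers
it computes and what they mean. A thin CLI mirrors the shell workflows:

```bash
neurocollin simulate out_dir --n-neurons 120 --kappa 8 --seed 1
neurocollin run image.tif mask.tif centerline.csv --out records.csv
neurocollin stats records.csv --out contrasts.csv
```

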