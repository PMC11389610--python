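# Methods

`neurocollin` quantifies how *collinear* the pyramidal neurons of a curved
cell layer are — how uniformly their somata point perpendicular to the
layer — starting from an instance-segmentation label mask of a Nissl-type
histological section. This note documents the model, the numerical
choices, the synthetic ground-truth generator, and the limits of what the
synthetic validation shows.

## Coordinate and angle conventions

Pixel coordinates are `(x = column, y = row)` with rows increasing
downward. Every angle is computed after sign-flipping the row axis, so
angles follow the mathematical convention (counter-clockwise from +x,
y-up). Orientations of line-like objects are *axial* — defined modulo
180° — and are folded into `[0, 180)`. The correction angle is
*directional*, in `[0, 360)`. Mixing the two is safe because the
corrected orientation is folded back into `[0, 180)` (see below).

## Image preparation

Raw sections (8-bit grey or RGB) are reduced to luminance
(ITU-R BT.709 weights 0.2126/0.7152/0.0722, configurable), inverted so
dark somata become bright, and contrast-stretched so the 0.35% /
99.65% intensity percentiles map to 0/255. The saturation fraction is a
common auto-contrast default and is configurable; the source protocol
states only that images were adjusted automatically. A constant image
cannot be stretched and is returned inverted with a warning.

## False-positive filtering

Instance segmenters applied to Nissl material produce four recognizable
classes of false positives. They are removed per partition, in a fixed
order, with one (first-triggered) reason code per excluded object:

1. **extracellular** — mean grey below the midpoint of the mean
   segmented-pixel and mean background-pixel grey values of the
   partition (computed on the prepared image, neurons bright). Run first
   because faint speckle would otherwise corrupt the size statistics.
2. **too_small** — equivalent-circle diameter below `mean − 0.75·SD`;
3. **too_large_diameter** — above `mean + 1.75·SD`;
4. **too_large_area** — area above `mean + 1.75·SD` of areas.

Size statistics (sample SD, ddof = 1) are computed over the survivors of
rule 1 *within the partition*, never pooled. Values exactly on a
threshold are kept: the thresholds are stated as deviations from the
mean without an equality convention, and keeping the boundary is the
conservative choice (unit-tested with diameter sets whose mean and SD
are exact in binary floating point). "Diameter" is operationalized as
the equivalent-circle diameter `2·sqrt(area/π)`; the ellipse minor axis
is a configurable alternative. With fewer than two survivors of rule 1
the SD is undefined and the size rules are skipped with a warning.

Note a structural property of SD-based trimming: on a contaminant-free
unimodal population, roughly the lower quartile of a clean diameter
distribution falls below `mean − 0.75·SD` regardless of the spread, so
a fraction of true neurons is always trimmed. This mirrors the behavior
of the original exclusion rules and is deliberately not "fixed".

## Orientation estimation

Each kept segment is summarized by the ellipse sharing its second
central moments. Pixel centres are treated as unit squares (the +1/12
Sheppard term), so one-pixel-wide objects still have positive width.
For a uniform filled ellipse the variance along a semi-axis `a` is
`a²/4`, hence full axis lengths are `4·sqrt(eigenvalue)`. The
uncorrected orientation **UncO** is the principal-eigenvector angle
folded into `[0, 180)`. Moment matching (rather than outline least
squares) is robust for filled blobs and reproduces the behavior of the
"fit ellipse" of common image tools.

Orientation is meaningless for near-circular objects: fits with
`(major − minor)/major < 10⁻³` are marked invalid, and an eccentricity
gate (`major/minor ≥ 1.05` by default) excludes near-isotropic objects
from orientation analyses while keeping them in counts. The gate and
its default are this package's addition; the source protocol is silent
on near-circular somata. Objects with fewer than 3 pixels or a singular
moment matrix are flagged rather than silently assigned an angle.

Render-and-recover tests on 30-px 2:1 ellipses give an RMS angular
error below 1.5°; rotation of a pixel set changes UncO by the rotation
angle to within ~1° at that size (discretization).

## Curvature correction

The layer is curved, so UncO values are not comparable across a
partition. For each neuron the **correction angle CorrA** is the
direction from its centroid to the nearest point on a manually drawn
layer centerline (segment interiors included; ties broken toward the
lowest segment index for determinism). The **corrected orientation**
is

    CoO = (CorrA − UncO + 90°) mod 180°

A neuron whose major axis is parallel to the local layer normal scores
CoO = 90° on either side of the centerline — the mod-180 fold makes the
measure independent of which side the neuron lies on and of whether the
correction vector is taken centroid→line or line→centroid (a 180°
flip, absorbed by the fold; verified as a property test). A centroid
exactly on the centerline has no defined direction; the local centerline
normal is substituted and the record flagged.

The defining property, tested end-to-end, is rotation invariance:
rigidly rotating mask plus centerline leaves every CoO unchanged to
within rasterization tolerance (< 2° for ~30-px somata).

## Collinearity measures

For a set of CoOs:

* **dev** — mean angular deviation: mean axial distance from the 90°
  perpendicularity reference, in `[0, 90]`. This follows the reading of
  dev as anchored to the fixed 90° reference; the circular SD about the
  sample mean is a different quantity and is *not* what is computed
  here.
* **var** — circular variance `1 − R̄`, with `R̄` the mean resultant
  length of the *angle-doubled* CoOs. Doubling is the standard
  treatment for axial (period-180°) data; a raw-angle mode
  (`axial=False`) exists for strict replication of tools that skip it.
  `var = 0` means perfect alignment; `{0°, 45°, 90°, 135°}` doubles to
  the four cardinal directions and gives exactly 1.

Pooling partition summaries to subregion level supports both
neuron-weighted and partition-weighted means, labeled with the mode,
since the original reduction is not stated.

Rose histograms use half-open bins over `[0, 180)`; orientation-line
plots sample one neuron uniformly at random (seeded) per occupied
220 × 220 µm grid square and draw a fixed-length segment along the
chosen angle.

## Group statistics

Neuron-level angular deviations are transformed per *slide*
(anterior–posterior level) with a rank-based inverse-normal transform,
`z = Φ⁻¹(r/(n+1))` with average ranks for ties (the `(r−0.5)/n` offset
variant is available). The transform is slide-local and
rank-preserving; slides with fewer than two observations are skipped
with a warning.

Subregions are compared with a linear mixed model on `z`: subregion as
fixed effect, random intercepts for case and slide (crossed by default,
nested available), fitted by maximum likelihood — REML likelihoods are
not comparable across fixed-effect structures, and the overall subregion
effect is a likelihood-ratio test against the intercept-only model
referred to χ²(k−1). Pairwise contrasts use a Tukey-design single-step
adjustment: `p_adj = P(max|Z| ≥ |z|)` under the joint multivariate
normal of the contrast statistics, estimated by seeded Monte-Carlo
(50 000 draws by default; Bonferroni fallback available, mode always
recorded). Adjusted p-values are clipped to never fall below the
unadjusted ones. The implementation is statsmodels `MixedLM` (variance
components on a single grouping of all rows, which expresses crossed
intercepts); it reproduces lme4 log-likelihoods, fixed effects and LRT
statistics to at least four decimals on a frozen test dataset.

### Calibration

`calibration_experiment` measures the operating characteristics by
simulation: balanced 8-subregion design, 5 cases × 5 slides crossed,
2 observations per cell (n = 400 per replicate), response drawn directly
on the model's input scale (unit residual SD; case and slide SDs 0.3).
Under the global null the LRT rejects at close to the nominal 5% and
the Tukey familywise error stays controlled. A full-chain variant
(degree-scale deviations, baseline 25°, residual SD 10°, truncated to
[0, 90], then per-slide quantile normalization) is also reported: the
rank transform perturbs the within-slide covariance slightly, so the
end-to-end chain can run a couple of points from nominal — a property
of rank-based pre-transforms worth knowing when interpreting borderline
p-values.

Power is benchmarked on the focused two-subregion comparison
(n = 400, 0.5-residual-SD shift), where it is essentially 1. The same
shift spread over a balanced 8-subregion design caps the LRT
noncentrality near 11 (df 7), i.e. power around 0.6–0.8 — reported
alongside, as a reminder that many-group omnibus tests dilute
single-group shifts.

## Synthetic scenes

The generator renders what the pipeline is built for: a curved lamina
(circular arc, sine, or line) of elongated somata oriented along the
local curve normal plus axial von Mises noise of concentration κ
(directional sampling at doubled angles, halved back — κ = 0 is axially
uniform, `None` disables noise). Defaults emulate a human-hippocampus
partition at 1 µm/px: 30 µm somata with 2:1 axis ratio (±10% length
jitter), an 80 µm-wide layer, dark somata (grey ≈ 40) on a light
background (≈ 220) with mild Gaussian texture noise (SD 2), as in a
raw Nissl photograph before preparation. Somata are placed stratified
along the curve (packing the layer like a real stratum pyramidale) with
rejection sampling and a 1-px minimum gap between objects; failure to
place after bounded retries raises an error advising lower density.
Label masks are rendered with hard edges (no antialiasing) so areas and
pixel sets are exact; triangles (pyramid-like somata) use the
apex-to-base-midpoint axis as true orientation.

Contaminants mimic the four false-positive classes: glia as 8 µm dark
discs, doublets as two merged somata under one label, speckle as
near-background-intensity patches. Every object's class, centroid, true
orientation, area and curve position are recorded; the label↔truth
mapping is bijective and the whole scene is a deterministic function of
the seed.

What the generator does **not** emulate: real Nissl texture and staining
gradients, segmentation errors other than the four planted classes
(e.g. boundary erosion, partial splits), anisotropic pixel sizes, and
3-D effects of section thickness. Passing the synthetic suite therefore
validates the *post-segmentation* pipeline — measurement, filtering,
orientation, curvature correction, statistics — not the external
segmenter, which is out of scope by design.

### Rigid-rotation resampling

Rotation-invariance experiments rotate the label mask nearest-neighbour
on an expanded canvas and the centerline vertices exactly, with the
same transform. When the rotation matrix is integral (quarter turns)
the translation is snapped to the pixel lattice, making the resampling
exact. The 1-px generation gap prevents boundary pixels from being
reassigned between touching labels under resampling.

## Problem sizes used in validation

Scenes of 100–200 somata on arcs of radius 500–700 px (canvases around
0.7–1.5 Mpx), 1000 rendered ellipses for orientation recovery, 50 random
small scenes for the filter contract, 1500 null replicates (plus 100-rep
power runs and a 250-rep full-chain diagnostic) for the statistical
calibration. A full validation run completes in a few minutes on one
CPU core.

## Known limitations

* The filter's SD thresholds assume a roughly unimodal size
  distribution per partition; heavily bimodal partitions (e.g. mixed
  layers) would need per-stratum partitions.
* dev is anchored at 90° by definition; a layer systematically tilted
  against its own centerline shows up as large dev, not as a shifted
  mean — by design, since perpendicularity is the reference.
* The curvature correction is 2-D and single-section; no attempt is
  made to correct for out-of-plane obliquity.
* Near-circular somata carry no axial information and are gated out of
  orientation statistics; their fraction is reported via `ecc_ok`
  rather than silently dropped.
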