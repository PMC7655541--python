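# Methods

This note records what each stage of the pipeline computes, the modeling
assumptions behind it, the default parameters (with units and rationale),
what the synthetic data does and does not emulate, and the numerical
choices and known limitations.

## Problem setting

The pipeline measures root-nodule phenotypes from RGB photographs of
excavated legume roots: it segments nodule pixels, cleans the masks,
counts connected components as nodules, converts pixel areas to mm²
through a physically calibrated mm-per-pixel scale, and feeds the
per-image counts and areas into a randomized-complete-block ANOVA with
subsampling. A semi-automatic annotation loop (predict → human-style
polygon correction → incremental retraining) reduces labeling effort.

All desk-scale numbers in this repository (128×128 scenes, depth-3
network, 3×3×30 phenotype tables) are the package's own test-bed
configuration; the same code runs at camera resolution (6000×4000 inputs
mapped to 1024×1024 network inputs) by changing parameters only.

## Synthetic scenes (`synth`)

Scenes emulate the *qualitative* structure of field photographs:

- dark soil background: base tone plus smoothed low-frequency blotches
  plus per-pixel Gaussian noise (`background_noise_sd`, default 8
  intensity units);
- thin branching root strands: downward random-walk polylines dilated to
  a sampled width (`root_width_range`, default 3–7 px), drawn in a
  lighter tan tone; roots are *background* in the mask;
- nodules: rotated ellipses (aspect 0.7–1.0) attached to root pixels,
  rendered as bright blobs; radius sampled from `nodule_radius_range`
  (default 6–14 px).

With probability `overlap_fraction` (default 0.3) a nodule is placed
touching an existing one; ground truth keeps one instance per placement
even when masks merge, so merged components are a *known* failure mode
of component-based counting, not an accident. The remaining placements
are pixel-disjoint; `min_separation` (default 0 px) additionally keeps
them that many pixels from existing foreground. Separation matters
because pixel-disjoint instances may still be 8-adjacent or within
closing range, in which case even a perfect mask yields fewer components
than instances — scenes meant to have exactly recoverable counts should
use `min_separation > 2*closing_radius + 1`.

Placement retries are bounded (200 per nodule) and exhaustion raises an
explicit error rather than silently dropping objects. Per-scene seeds in
`generate_dataset` derive from one `SeedSequence`, kept below 2³¹.

Not emulated: photorealistic soil texture, lighting variation, shadows,
occlusion by soil, camera optics, nodule color variation with maturity.
The generator's purpose is exact ground truth for every downstream
stage, not fidelity.

Phenotype tables follow the linear model
`y_ijk = mu + beta_j + alpha_i + delta_ij + eps_ijk` on the log scale
(block, treatment, plot, subsample effects), exponentiated to the
natural scale so a log-transformed analysis is the correct one. Defaults
(3 blocks × 3 treatments × 30 subsamples = 270 rows, `block_sd` 1.2
exceeding treatment effects 0–0.6) mirror the field layout where block
variation dominates.

## Preprocessing (`prep`)

Photographs of arbitrary size are mapped to the square network input by
one isotropic scale `target/max(H, W)` (aspect preserved), floor
rounding of the scaled dims, and centered constant padding (image mean
for RGB; zero for masks). RGB uses bilinear interpolation (with
anti-aliasing when downscaling); masks use nearest-neighbor in both
directions. The `TransformRecord` (original dims, scale, scaled dims,
pads, target) inverts the mapping exactly; `reconstruct` strips padding
and rescales content to the original grid.

Resampling limit: nearest-neighbor round trips confine errors to a
boundary band of roughly one scale factor. Consequently per-object IoU
after a round trip depends on the object-radius-to-scale-factor ratio:
measured on random disks, factor 1.5 with radius 30 px gives IoU ≥ 0.95,
but factor ~5.9 (6000→1024) caps radius-10 disks near IoU 0.75 — a
quantization bound that no resampling scheme can beat, since such a disk
spans only ~3.4 network pixels. Objects at least ~10 px radius *at
network resolution* stay above IoU 0.95 through the full-resolution
round trip. Originals no larger than the target lose nothing and
round-trip exactly.

## Segmentation network (`segnet`)

A U-Net-style encoder–decoder: `depth` resolution levels of two 3×3
convolutions + ReLU and 2×2 max pooling, a middle block, then mirrored
2× nearest-neighbor upsampling with skip concatenation, and a 1×1
output convolution producing foreground logits. Channel width doubles
per level from `base_channels`.

The implementation is pure numpy with hand-written backpropagation
(strided-view batched-GEMM convolutions); gradient correctness is
verified by directional derivative checks in the test suite's training
behavior (loss decrease, data fitting). Training minimizes a summed
soft-Dice + binary-cross-entropy loss on logits with Adam; minibatch
order is drawn from a seeded generator so training is bit-reproducible.

Desk defaults: `input_size` 128, `depth` 3, `base_channels` 16,
learning rate 3e-3, batch size 4, 30 epochs — chosen so a full training
run takes tens of seconds on one CPU while still reaching held-out F1
above 0.9 on desk scenes. `update` continues optimization from the
current weights on the union of remembered and new pairs (replay), which
is the transfer-learning half of the annotation loop; replay prevents
catastrophic forgetting of earlier training data.

## Post-processing (`postprocess`)

Order is fixed: CRF refinement and threshold/closing/fill at network
resolution → reconstruction to original resolution → (optional
annotation corrections) → component labeling → size filtering.

The fully connected CRF uses mean-field inference with two Gaussian
pairwise kernels: appearance (weight 10, color sd 13 intensity units,
position sd 80 px) and smoothness (weight 3, position sd 3 px) — the
reference defaults of the published dense-CRF method. Unary energies
are negative log network probabilities. The appearance kernel is
approximated by a 5-D bilateral grid (splat, unit-σ Gaussian blur,
slice, with multilinear interpolation over the 2⁵ cell corners); the
smoothness kernel by a truncated Gaussian filter. Messages exclude each
pixel's self-contribution and are normalized by the kernel mass
`S(1) − 1`, so label updates are convex combinations and the
zero-weight limit reproduces the input probabilities exactly (tested).
Label probabilities update via a numerically stabilized softmax.

Thresholding is inclusive at `prob_threshold` (default 0.5). Closing
uses a disk of `closing_radius` (default 2 px) followed by interior
hole filling; both only add foreground. Component labeling uses
8-connectivity by default. The size filter removes components outside
inclusive pixel bounds; the lower bound is expressed physically
(`min_component_mm2`, default 1 mm²) and converted by
`ceil(mm² / mm_per_pixel²)` so the same setting works at any
resolution.

## Measurement (`measure`)

Areas are exact pixel counts times `mm_per_pixel²`, measured on the
reconstructed full-resolution mask; a merged blob counts as one nodule
by design. Each component record carries pixel count, area, centroid,
bbox, and its outer contour (marching squares at the 0.5 level).
`calibrate_scale` derives mm-per-pixel from a reference object of known
physical length in the image frame. Per-image rows aggregate count,
total area (mm² and cm²), and mean area (undefined/None for zero
nodules, kept distinct from 0).

## Annotation loop (`annotation`, `evaluate`)

Masks convert to one outer contour polygon per 8-connected component
(marching squares at 0.5, so polygons run between pixel centers);
polygons rasterize back via filled-polygon scan conversion, unioning
overlaps. Corrections merge as
`(predicted ∪ add) \ remove` — removal wins on conflict. Files use a
LabelMe-compatible JSON dialect (`shapes` of type `polygon`, points as
(x, y) = (column, row), label `nodule`, provenance in `description`).

The correction-loop harness replaces the human: each round it predicts
on fresh scenes, scores them, corrects the k worst by adding the
ground-truth contours and removing contours of the false-positive
region (so true-positive area is never deleted), and updates the model.
Pixel metrics are precision `TP/(TP+FP)`, recall `TP/(TP+FN)`,
`F1 = 2PR/(P+R)`; when both masks are empty all three are 1, and a
prediction with `TP = 0` otherwise scores 0. Image sets aggregate by
macro-averaging per-image F1 (default) or by pooling counts (micro).

## Statistics (`stats`)

The RCBD-with-subsampling ANOVA is computed from explicit sums of
squares (blocks, treatments, block×treatment interaction as
experimental error, within-plot sampling error) with degrees of freedom
`b−1`, `t−1`, `(b−1)(t−1)`, `bt(s−1)`. The treatment F statistic uses
the experimental-error mean square as denominator — never the sampling
error, because subsample plants within a plot are not independent
replicates of the treatment. Only balanced designs are accepted
(explicit error otherwise). Log transformation is applied on request
with an error naming non-positive rows.

Tukey comparisons use the studentized range with
`SE = sqrt(MS_exp/(b·s))` and the experimental-error degrees of
freedom. Per-treatment Pearson correlations report r, p, significance
stars (0.05/0.01/0.001), and n; constant traits give missing r. An
optional weighted plot-means path models plot-mean variance
proportional to a power of the fitted values (iterated WLS); at power 0
it reduces to the ordinary plot-means analysis, whose treatment F
equals the subsampling ANOVA's (tested identity). Diagnostics return
QQ data and a Shapiro–Wilk p-value on the plot-level residuals plus
per-observation fitted-vs-residual pairs.

## Numerical choices

- float32 network arithmetic (memory/throughput), float64 elsewhere;
- convolutions via nine shifted strided views and batched GEMM — no
  im2col materialization;
- stable sigmoid/softmax throughout; Dice loss smoothed with ε = 1;
- CRF message normalization by `S(1) − 1` with floors at 1e-12;
- all stochastic stages seeded; derived seeds from `SeedSequence`,
  reduced mod 2³¹.

## Limitations

- The synthetic generator is a test bed, not a camera model; absolute
  F1 values on it do not transfer to field images.
- Instance splitting of merged nodules is deliberately out of scope; a
  merged blob is one component (known failure mode).
- Heavy downscaling erodes small-object fidelity (see the resampling
  limit above); at camera scale, objects below ~10 network pixels of
  radius cannot be measured accurately after reconstruction.
- The ANOVA layer covers the balanced classical case only; unbalanced
  data are rejected rather than approximated.
- The numpy network is CPU-bound and desk-scale; it is a faithful,
  testable implementation, not a performance claim.
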