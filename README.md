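# nodulepipe

Deep-learning measurement of root nodules from photographs of excavated
legume roots, with the statistics to turn those measurements into field
conclusions.

Nodule count and nodule size are the standard proxies for biological
nitrogen fixation capacity, but hand-counting nodules on photographed
root systems is slow and subjective. This package implements the full
measurement pipeline:

- **`synth`** — a synthetic scene generator (soil background, branching
  roots, bright elliptical nodules) with exact per-instance ground
  truth, plus a simulator for randomized-complete-block phenotype
  tables; this is the test bed for every downstream stage.
- **`prep`** — invertible mapping between arbitrary photograph sizes
  and the square network input (isotropic scale, centered padding,
  recorded transform).
- **`segnet`** — a U-Net-style encoder–decoder segmentation network,
  implemented in pure numpy with hand-written backpropagation, trained
  with a soft-Dice + cross-entropy loss; supports incremental `update`
  for transfer learning.
- **`postprocess`** — fully connected CRF refinement (mean-field with a
  bilateral-grid appearance kernel), thresholding, morphological
  closing and hole filling, component labeling, physical size
  filtering.
- **`measure`** — per-nodule and per-image measurements (counts, mm²
  areas, centroids, contours) through a calibrated mm-per-pixel scale.
- **`annotation`** — polygon annotations (LabelMe-compatible JSON),
  mask↔polygon conversion, and correction merging, so a human can fix
  predictions instead of labeling from scratch.
- **`evaluate`** — pixel precision/recall/F1, learning curves, and a
  scripted predict→correct→update loop that quantifies how fast the
  model improves from corrections.
- **`stats`** — RCBD-with-subsampling ANOVA (treatments tested against
  the experimental-error stratum, never the subsampling error), Tukey
  pairwise comparisons, per-treatment trait correlations, weighted
  plot-means fits, and residual diagnostics.

`docs/methods.md` documents the model and assumptions of each stage,
all default parameters with units, and known limitations.

## Worked example

Train on a dozen synthetic scenes, then run the full online path —
predict, CRF, closing, reconstruction, component detection, size
filter — on fresh scenes and compare against ground truth
(`examples/train_and_measure.py`):

```
training on 12 synthetic scenes ...
final training loss: 0.0179

scene                    count             area mm^2
scene_1637642055      4 / 4          153.5 / 152.0
scene_1737410015      4 / 4          124.8 / 123.8
scene_79167534        4 / 4           99.0 / 98.0
scene_830313125       4 / 4          132.5 / 132.5
scene_869225620       4 / 4          162.8 / 161.2

(measured / ground truth; areas from pixel counts x mm_per_pixel^2)
```

The annotation loop (`examples/correction_loop.py`) starts from a model
trained on only four scenes and corrects the two worst predictions per
round through the polygon layer:

```
initial training on 4 scenes, then 3 predict->correct->update rounds ...
 round       f1  n_train_pairs
     0 0.000000              4
     1 0.852951              6
     2 0.868067              8
     3 0.963581             10

held-out F1 gain over the loop: +0.964
```

The statistics layer (`examples/phenotype_anova.py`) fits the
log-transformed nested ANOVA on a simulated 3-block × 3-treatment ×
30-subsample table, testing treatments against the plot stratum, and
follows up with Tukey comparisons, correlations, and normality
diagnostics. `examples/generate_scenes.py` shows dataset generation
with on-disk image/mask/sidecar triples.

The same operations are available from the command line:

```
nodulepipe generate --out scenes/ --n 12 --seed 101
nodulepipe train --scenes scenes/ --model model.npz --epochs 30
nodulepipe predict --model model.npz --image scenes/scene_X.png --out prob.npy
nodulepipe measure --mask mask.png --mm-per-pixel 0.5 --out rows.csv
nodulepipe stats --phenotypes table.csv --trait trait --log
```

Run `nodulepipe <command> --help` for the full set (generate, train,
update, predict, postprocess, correct, export-contours, measure,
evaluate, stats).

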