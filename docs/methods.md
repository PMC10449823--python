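# Methods

## The problem and the method

Closed-set individual identification: every image shows exactly one animal
from a fixed roster of K individuals (one softmax unit per animal), and
the identity signal is the animal's coat pattern seen from above.
Labeling farm imagery by hand is expensive, while unlabeled snapshots
accumulate for free, so the package implements iterative
confidence-threshold pseudo-labeling (self-training):

1. Train a classifier on the manually labeled pool.
2. Predict softmax confidences on the remaining unlabeled pool.
3. For each candidate threshold t in a fixed grid, train a fresh
   classifier on {labeled} ∪ {previously promoted} ∪ {unlabeled images
   whose confidence is strictly greater than t, taking the predicted
   class as label}, and score it on the validation set.
4. Keep the threshold whose model has the highest validation accuracy
   (ties go to the *largest* threshold — fewer, cleaner pseudo-labels is
   the conservative side), promote its filtered records, and repeat from
   step 2 with that model.

The confidence is σ(z)ᵢ = e^{zᵢ} / Σⱼ e^{zⱼ} evaluated at the winning
class; the default grid is {0, 0.5, 0.75, 0.90, 0.95, 0.98, 0.99, 0.995,
0.999, 0.9999, 0.99999, 0.999999, 0.9999999}. Threshold 0 admits every
prediction (softmax confidences are strictly positive) and the upper tail
probes the extreme of the float64 softmax scale.

Key policy decisions, each of which was genuinely open:

- **Frozen pseudo-labels.** Once promoted, a record's label never changes
  and the snapshot leaves the unlabeled pool. The alternative (re-predict
  everything each round) is coherent but makes the training-set
  composition non-monotone; the frozen policy gives monotone pseudo-pool
  growth and is what the multi-round bookkeeping here assumes.
- **Strict inequality** at the threshold ("confidence above t"), so the
  boundary case never promotes.
- **Fresh initialization** of every model in every sweep — no warm
  starts; a sweep entry is a function of its training set and seed only.
- **Early stop** when the winning threshold promotes zero images;
  continuing would re-train the identical model indefinitely.
- **Equal weight** for manual and pseudo-labels in the loss. The known
  alternative (an α-weighted unlabeled term with a ramp schedule) couples
  all unlabeled data into every update; threshold filtering instead
  excludes low-confidence data outright.

Training seeds are derived as hash(master seed, digest of the training
set contents). Consequence: two thresholds that filter identical
training sets provably train identical models, so the sweep caches such
duplicates instead of retraining — this is what makes the 13-point grid
affordable on one CPU core, and it is the scientifically right
invariance (the model should depend on the data and seed, not on which
grid index produced the data).

## Classifier

The classifier contract is four methods: `initialize(seed)`,
`set_trainable_scope("head"|"all")`, `fit`, `logits`. Training is always
two-stage: a feature-extraction stage updating only the two
fully-connected head layers, then a fine-tuning stage with everything
unfrozen. Two backbones ship:

- **small-cnn** — three 3×3 conv blocks (6/12/24 channels; conv→ReLU→
  2×2 max-pool twice, then conv→ReLU→global average pooling) and a
  48-unit FC layer feeding the K-way softmax, implemented in numpy with
  hand-written backprop and Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8),
  mini-batches of 16. Inputs are standardized per image (zero mean, unit
  std), which makes the network invariant to multiplicative gain — the
  dominant nuisance in infrared imagery and the reason the strong
  brightness augmentation below is survivable without normalization
  layers. Gradients are verified against central differences in the test
  suite.
- **nearest-centroid-reference** — logits are −τ · (mean squared distance
  to each class's mean image), τ = 100. Fitting is deterministic and
  seed-free, so engine tests that assert bit-identical histories run
  against it; it is a reference for *reproducibility*, not a performance
  baseline.

Default schedule: 10 head-only epochs + 60 full epochs, both at Adam
learning rate 2e-3. The classical transfer-learning schedule (30 + 60
epochs at 1e-3 then 1e-5) presumes an ImageNet-pretrained backbone whose
fine-tuning stage only nudges good features; with a from-scratch
backbone the second stage *is* the fit, and a 100×-reduced rate leaves
the model at chance. The head-only stage is retained as a warm-up so the
freeze semantics (and the `stage2_epochs = 0` degenerate case) are
exercised exactly as specified. Defaults were chosen so the desk-scale
baseline is competent but unsaturated — an underfit classifier has
uninformative confidences, and a saturated one leaves pseudo-labeling
nothing to improve; both would make the method itself unobservable.

Augmentation (training only, never at prediction): zoom uniform in
[0.9, 1.1], brightness multiplier uniform in [0.2, 1.5], horizontal and
vertical flips each with probability 0.5, nearest (edge-clamp) fill.
Zoom uses nearest-neighbour resampling about the image centre.
Intensities clip at the sensor ceiling after brightness scaling.

## Synthetic data generator

The generator stands in for a rig of top-down depth/infrared cameras
over milking-parlor exit lanes. What it emulates:

- **Identity signal**: each individual's coat is a fixed binary pattern
  (union of random smooth blobs thresholded to a 30–55% dark fraction)
  on an elliptical body of aspect 2.2; patterns with pairwise dark-patch
  IoU > 0.85 are redrawn, so individuals are distinguishable by
  construction.
- **Capture geometry**: 96×128 frames (desk-scale stand-in for 640×480),
  background depth plane exactly at the 3500 mm camera height, body
  surface near 2000 mm (a cow's back below a 3.5 m camera) with a smooth
  dome toward the spine and σ = 20 mm depth jitter, clipped positive.
- **Pose and nuisance variation**: heading flips 180° at random (cows
  walk the lane both ways), orientation jitter ±30°, zoom jitter ±8%,
  lateral offset ±8 px, per-snapshot brightness 0.85–1.15, per-day
  illumination gain 0.8–1.2, pixel noise σ = 8 (8-bit scale).
- **Study structure**: multi-day sessions; train/validation/test/
  unlabeled splits assigned purely by capture day and pairwise
  day-disjoint (models are always tested on unseen days, which the
  day-level illumination gain makes a real distribution shift);
  class-balanced validation and test budgets (an indivisible budget is a
  configuration error); a hidden ledger keeps the true identity of every
  unlabeled snapshot so pseudo-label precision is scoreable.

Per-snapshot seeds derive from (master seed, individual, day, index), so
any manifest re-renders bit-exactly from its configuration.

What it does **not** emulate — and hence what passing tests cannot show
about real data: occlusion and touching animals, perspective and lens
distortion, segmentation-mask errors (masks here are exact by
construction; a real pipeline takes them from a trained segmenter), coat
change over time, open-set arrivals/departures, and any realistic
depth-sensor artifact structure (holes, speckle). Results on this
generator demonstrate the *mechanics* of the pipeline — filtering,
selection, bookkeeping, and the qualitative benefit of pseudo-labeling —
not field performance.

## Preprocessing

A snapshot is triggered when the mean depth over a lane region is
*strictly* below the 3000 mm threshold (the empty lane at 3500 mm never
fires; boundary equality never fires; all ROI pixels count — no
invalid-pixel masking). The infrared image is masked (background pixels
exactly 0), the foreground's principal axis is estimated from second
central moments of the mask coordinates (angle in (−90°, 90°],
counter-clockwise positive, 0 by convention for equal eigenvalues), and
image + mask are rotated by the negative of that angle with
nearest-neighbour interpolation, re-masked, and cropped to the tight
foreground box plus padding (default 2 px, clipped at the frame).
Nearest-neighbour plus re-masking keeps "background is exactly zero" an
exact invariant rather than an approximate one. The 180° head-left/
head-right ambiguity of a principal axis is deliberately left
unresolved: horizontal flips during augmentation absorb it. Crops are
finally resized to the classifier geometry (default 16×32) with
anti-aliasing and scaled to [0, 1].

## Evaluation

- **Accuracy** — correct / total; the headline metric because validation
  and test sets are class-balanced.
- **mAP** — the *macro* mean over classes of one-vs-rest average
  precision with step interpolation (area under each class's
  precision-recall curve when images are ranked by that class's score).
  Every class must appear in the truth at least once, otherwise its AP
  is undefined and the metric refuses rather than guessing.
- **Improvement statistics** — absolute gain in percentage points and
  relative gain in percent of baseline, from a (baseline %, final %)
  accuracy pair.
- **Labeled-fraction ablation** — the labeled pool is subsampled
  class-proportionally (floor + largest-remainder per class so the
  global total is exact; a class that would get zero keeps one image,
  with a warning) and each fraction seeds a full pseudo-labeling run;
  rows report train sizes, test accuracies, relative gain, and the
  percentage of all training-side images (full labeled pool + unlabeled
  pool) utilized before and after.

## Problem sizes and determinism

The default desk-scale study is 15 individuals, 2 labeled training
images each, 400 unlabeled, 60 validation + 60 test (4 per individual,
day-disjoint), 96×128 frames, classifier input 16×32, two pseudo-labeling
rounds — sized so a full run takes tens of seconds on one CPU core and
the 10-seed acceptance experiment a few minutes. Engine tests run
against the reference backbone and assert bit-identical round histories
across repeated runs. The CNN path is deterministic for a fixed seed and
a fixed BLAS; all randomness flows through seeds derived from the master
seed with sha256, never through global RNG state.

## Known limitations

- The 16×32 input and a three-block CNN cap achievable accuracy; the
  backbone is pluggable (`ClassifierSpec`) for anyone wanting a real
  pretrained network at full resolution.
- The threshold sweep re-trains per distinct filtered set; its cost is
  linear in the number of distinct grid cells, which is fine at desk
  scale but would want parallelism at herd scale.
- `crop_rotate` records its crop box in the rotated frame (rotation with
  `reshape=True` changes the frame), so the box is not directly an index
  into the source image.
- The ablation keeps one image for classes that would round to zero,
  which can push the realized subsample slightly above the requested
  fraction on very small pools.
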