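# Methods

This note documents the models and procedures implemented in `leafara`, the
parameter choices that matter, what the synthetic data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Artificial Rabbits Algorithm (`leafara.ara`)

ARA is a population metaheuristic for bound-constrained minimization.
Per rabbit and per iteration the algorithm draws the random bundle
(R1, R2, R4, R5, R6 uniform on [0,1]; n1 a per-dimension standard normal;
n2 a scalar standard normal; g a random permutation of the dimensions) and
computes the energy factor E = 4(1 − t/T)ln(1/R4). With E above the
threshold (default 1.0) the rabbit takes a detour-foraging step against a
uniformly chosen peer j ≠ i; otherwise a random-hiding step toward a fresh
burrow. Candidates are clipped to the box; selection is greedy
(keep the candidate iff its objective does not exceed the incumbent's),
which makes the best-so-far trace provably non-increasing — the property
the test suite asserts.

Decisions taken where the recipe is underdetermined:

- **Peer choice.** The exploration step needs a second position X_j; it is
  sampled uniformly from the other rabbits, the convention of the original
  rabbits-optimization literature.
- **Dimension selector c.** c keeps the first max(1, ⌈R·D⌉) entries of the
  permutation g, guaranteeing at least one moving dimension; the selector
  fraction reuses the R1 draw.
- **The rounding offset.** `round(0.5·R1)` is evaluated literally by
  default (`round_mode="printed"`, round-half-away-from-zero), where it is
  almost surely zero; `round_mode="aro_compat"` uses
  `round(0.5·(0.05 + R1))` so the +1 offset fires whenever R1 ≥ 0.95,
  matching the behaviour of reference implementations. The default favours
  printed fidelity; the compat mode is one flag away.
- **Burrow index.** ⌈R6·D⌉ with clamping to [1, D].
- **Energy threshold.** E > 1 selects exploration; since E decays linearly
  in t in expectation, exploration dominates early and exploitation late
  (asserted by regressing exploration counts on t over 30 seeds).
- **n1/n2 dimensionality.** n1 is drawn per dimension (a scalar would
  collapse the exploration step to a rigid translation); n2 is a scalar
  since the burrow perturbs exactly one dimension.
- **R4 scope.** Energy is redrawn per rabbit per iteration, giving each
  rabbit an independent explore/exploit decision.

## Synthetic leaf generator (`leafara.synth`)

Each image is a smooth leaf blob — an ellipse whose radius is modulated by
low-order angular harmonics — textured green over a dry-soil background,
with the binary mask exactly covering the blob. Ten phenotype classes are
rendered with distinct lesion morphologies: none (TH), viral mottling
(TMV), large necrotic patches (TEB, TLB, TTS), dark spots (TBS, TSLS),
olive mold texture (TLM), marginal yellowing with streaks (TYLCV), and
pale stippling (TTSSM), each with a small class-specific colour shift.
Canonical per-class inventory counts for the emulated collection are
shipped as `PLANT_VILLAGE_COUNTS` (summing to 18,161) and drive the
dataset-arithmetic checks.

Generation is a pure function of (spec, size, seed): per-sample seeds are
spawned from the master seed with `numpy.random.SeedSequence`. Default
canvas is 64×64 in tests and demos (256×256 and 224×224 remain available
through the resize operation).

What the generator does *not* emulate: real leaf venation, specular
lighting, occlusion, soil clutter, camera noise statistics, or intra-class
disease-stage variation. Passing tests therefore demonstrate that the
pipeline's machinery works end to end and that each stage recovers known
structure; they do not certify accuracy on real field images.

## Preprocessing and augmentation (`leafara.preprocess`)

- **Z-score normalization** uses per-channel population mean/std computed
  from the training split only; a zero-variance channel raises an error.
- **Augmentations** draw uniformly from the stated ranges: rotation 5–15°
  with random sign, magnification 2.5–10 %, translation 5–20 % per axis
  with random sign, additive Gaussian noise (default σ = 8 grey levels —
  visible but far from overwhelming an 8-bit image). Masks receive exactly
  the geometric transform of their image (nearest-neighbour, re-binarized);
  exposed borders are filled with the synthetic background colour, or by
  edge replication for ingested images.
- **Balancing** samples exactly 300 rows per class without replacement
  (configurable); **augmentation planning** adds 4 variants per balanced
  row as manifest rows carrying full transform records, so the
  3,000 → 12,000 → 15,000 arithmetic is exact and cheap, and images are
  materialized lazily by replaying the records.
- **Splitting** assigns 70:15:15 per class to *parent* rows by
  largest-remainder apportionment (per-class deviation ≤ 1 sample);
  augmented rows inherit their parent's split, so no image appears in two
  splits in transformed disguise. An optional inner 90/10 carve-out of the
  train split is available.

## Modified U-Net (`leafara.unet`) and the CNN engine (`leafara.nn`)

The segmenter follows the classic U-Net layout: encoder blocks of two 3×3
convolutions with batch normalization and ReLU, 2×2 stride-2 max pooling,
a bottleneck block, then a decoder using 2×2 stride-2 transposed
convolutions with concatenated skip connections, a 1×1 convolution head
and per-pixel two-class softmax. Defaults: depth 2, base width 8 — about
29k parameters, sized to the synthetic task.

Training uses mini-batch Adam at the published learning rate 0.002 and
batch size 16. The loss is selectable: NLL on the log-softmax of the true
class, or BCE / MSE on the foreground-probability channel (probabilities
below 1e-12 are clamped and logged). Early stopping halts after `patience`
(default 5) consecutive epochs without validation-loss improvement and
restores the best-validation-epoch weights, batch-norm running statistics
included. Predicted masks binarize by argmax over the two-class softmax.
Stratified k-fold cross-validation is provided as a driver that hands
fold indices to a caller-supplied train/eval closure.

The engine (`leafara.nn`) implements conv (im2col + BLAS matmul, with the
input gradient computed as a same-padding correlation with the flipped
kernel), batch norm, pooling, transposed conv, dropout, global average
pooling, dense layers and Adam, in float32 NCHW. Every layer's backward
pass is verified against finite differences in the test suite. It is
deliberately minimal: stride-1 'same' convolutions, 2× pooling/upsampling
only — exactly what the two architectures here need.

## Classification and hyperparameter search (`leafara.classify`)

Three evaluation cases: (1) healthy vs unhealthy (nine disease classes
collapsed), (2) six classes (TH, TSLS, TBS, TLB, TTS, TYLCV), (3) all ten.
The classifier is the U-Net encoder followed by global average pooling,
dropout and a dense softmax head; global pooling makes it input-size
agnostic. Training minimizes cross-entropy (the two-class case is
binary cross-entropy) with the same Adam/early-stopping scheme.

The search space is typed and encoded into the unit box: learning rate
log-uniform [1e-4, 1e-1], batch size ∈ {8, 16, 32}, dropout uniform
[0, 0.5], weight decay log-uniform [1e-6, 1e-2]. ARA searches the unit
box; positions decode to valid configurations everywhere. The objective is
the validation loss of a short proxy run (narrow model, few epochs, data
subset) — smoother than accuracy and cheap enough that the total
evaluation count N·(T+1) stays within an explicit budget. The selected
configuration is then retrained in full. Macro averaging is used for
precision/recall/F1 since class supports are balanced by design; a class
absent from the evaluated labels contributes zero with a warning.

## Score-CAM (`leafara.scorecam`)

For a chosen layer (default: the classifier's last encoder block), each
activation channel is bilinearly upsampled to input size, min-max
normalized, and used to mask the input multiplicatively. The weight of a
channel is the increase of the target-class probability of its masked
input over the all-zeros baseline; weights are softmax-normalized across
channels (raw weights available via a switch), and the heatmap is the
ReLU of the weighted sum, min-max normalized to [0, 1]. Only forward
passes are used. Overlays alpha-blend a colormap onto the image with
per-pixel weight proportional to heat, so zero-heat pixels show the
untouched image.

A practical note on the deletion check (zeroing the top-heat 20 % of
pixels should lower the class score more than zeroing a random 20 %): for
classifiers trained on clean images only, scattered random occlusion is
strongly out-of-distribution and disrupts the network as much as removing
the salient region. Classifiers trained with the pipeline's own
augmentation stack (noise and rotation variants) — the intended training
condition — are robust to scattered perturbation, and the deletion check
then passes decisively, alongside inside-mask localization. The test
fixtures therefore train under the augmented condition.

## Pipeline (`leafara.pipeline`, `leafara.cli`)

Stages run in a fixed order (synth → augment/split → segment → HPO →
classify → Score-CAM); each stage records its config hash, input/output
manifest hashes and seed. One global seed fans out per stage as
`sha256(seed ":" stage) mod 2^31`, so reruns reproduce manifests
bit-identically. Configuration is YAML with strict validation (unknown
sections or keys are rejected). Images and masks are PNG, manifests and
metrics CSV, configs/results YAML/JSON. Demo-scale defaults (10 images per
class at 32×32, depth-2 networks, a 3×2 ARA budget) complete in about a
minute; all sizes are configurable upward.

## Problem sizes and limitations

The shipped evaluations use 200 synthetic 64×64 leaves for segmentation
(test Dice ≈ 0.99 against an all-foreground baseline of ≈ 0.50) and a
balanced 120-image healthy/unhealthy set at 32×32 for classification and
saliency — sizes at which the full pipeline, including the ARA search,
runs in minutes on a single CPU. Known limitations: the CNN engine is
single-threaded beyond BLAS and unsuitable for large images or deep
models; the synthetic images are schematic (see above); k-fold
cross-validation re-trains from scratch per fold and is the most expensive
operation at larger sizes; and the headline accuracies reported for the
real Plant Village collection in the literature are out of scope here —
they require the external dataset and GPU-scale training.
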