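# Methods

## Scope and data model

The package segments sagittal spine MRI volumes into background plus one
label per vertebral body and intervertebral disc. All arrays follow the
axis convention (depth, height, width) = (sagittal slice index,
cranio-caudal, antero-posterior), 0-based. A `Volume` is a 3D float grid
with optional mm spacing; a `LabelMap` is an integer grid with values in
`[0, num_classes)`; a `SpineSample` pairs the two and records provenance
(`real` or `phantom`).

## Preprocessing

1. **Centered width crop.** The spine sits mid-image antero-posteriorly, so
   a box spanning the full depth and height but only the central
   `crop_width_fraction` (default 0.5) of the width is kept. The crop width
   rounds half-to-even; when the discarded width is odd the extra voxel is
   dropped from the high-index side. This tie-break is arbitrary but fixed
   and tested.
2. **Isotropic resample + symmetric pad** to the target grid (default
   18×256×128). One shared factor `f = min_i(target_i / size_i)` scales all
   three axes — per-axis factors would distort vertebral aspect ratios —
   followed by symmetric zero padding (background padding for labels).
   Intensities use trilinear, labels nearest-neighbor interpolation; label
   values are never interpolated into new values. An input already at the
   target shape passes through voxel-identically.
3. **Per-volume z-score** over all voxels (not per-slice, not
   dataset-level; background air is included). A constant volume maps to
   all zeros with a warning rather than dividing by zero.

The chain is deterministic and applies byte-identical geometry to volume
and labels. Cropping is inherently non-idempotent for fractions below 1
(it removes real content on a second application); the resample/pad and
normalization stages are idempotent to interpolation tolerance.

## Network

See the README for the block diagram. Implementation decisions that were
genuinely open:

- **Encoder schedule.** The stem runs at `base_channels/2` and the first
  strided CBR reaches `base_channels` (the minimal ramp consistent with the
  three 128-channel pyramid levels). After the mid-level block, two
  stride-1 residual blocks are followed by three dilated CBR blocks with
  in-plane dilations 2, 2, 4 (padding matched); the **first** dilated block
  carries the final (1,2,2) stride. This is the only schedule in the family
  considered that both honors "depth is never downsampled" and lands the
  high-level map exactly at (D, H/16, W/16).
- **Resolution convention.** The low-level map is the highest-resolution of
  the three (D, H/4, W/4) and the decoder works on the low-level grid.
- **Attention gates.** Both attention modules add their output through a
  learnable scalar initialized to 0 — standard for this attention family —
  so the network equals its backbone at initialization and identity
  behavior is testable exactly. Position attention refuses grids with
  N = D·H·W > 8192 rather than silently materializing an N×N matrix.
- **Channel gate.** The scene gate `σ(GAP(F_h'))` is spatially degenerate
  (1×1×1), so position attention on it is vacuous; it is processed by
  channel attention only.
- **Multiscale fusion cascade.** "Element-wise addition on each branch" is
  implemented as a cascade (branch *i* consumes branch *i−1*'s output,
  Res2Net style); a per-branch self-addition would be a no-op.
- **ASPP pool branch** uses a 1×1×1 convolution + ReLU without batch norm:
  normalizing a single spatial location over small batches is degenerate
  (the batch statistic has zero variance in the common batch-size-1
  evaluation case).
- **Classifier head.** 1×1×1 convolution to `num_classes` on the
  concatenated decoder features, then trilinear upsampling to the input
  grid — the lightest head consistent with emitting scores at input
  resolution.
- Batch norm uses mini-batch statistics in training (running estimates
  updated with momentum 0.1, biased variance) and running statistics in
  eval; convolutions use He-normal initialization seeded per model, so two
  models with the same seed are parameter-identical.

## Numerical stack

The neural network runs on `safnet.nn`, a compact reverse-mode autograd
engine over numpy arrays written for this package. 3D convolution is one
strided-view im2col plus one GEMM; its backward recomputes the column
matrix instead of caching it, trading a second memory pass for a flat peak
footprint (a full-scale forward stays under ~2 GB). Batch normalization
has a fused hand-written gradient. Every differentiable op is verified
against central finite differences in float64. Arithmetic is float32 in
the network; determinism holds to bit level for fixed seeds on a given
BLAS.

## Loss and metrics

- The training loss is the literal per-voxel-per-class **binary**
  cross-entropy mean over softmax probabilities (clipped to
  `[1e-7, 1−1e-7]`), i.e. every class contributes both its positive and
  negative terms, divided by H·W·D·C. A categorical cross-entropy variant
  is provided (`categorical_ce_tensor`) for comparison runs; the binary
  form is the default.
- **DSC** per class with the convention: both masks empty → 1.0 (structure
  correctly absent), exactly one empty → 0.0. This keeps per-class means
  defined on phantoms missing a structure.
- **MSD**: surface voxels are class voxels with at least one six-connected
  non-class neighbor (array borders count as outside); the distances of
  all surface voxels of both masks to the nearest opposite-surface voxel
  are pooled and averaged. A class absent from either map is reported as
  missing, never as 0. Distances use the Euclidean distance transform and
  scale linearly with voxel spacing.
- Aggregates are mean ± **sample** (n−1) standard deviation, formatted as
  percentages to two decimals; a single row reports sd 0 by convention.

## Training protocol

Adam with lr 1e-3 and L2 weight decay 1e-4 added to the gradient, batch
size 8, 50 epochs. The plateau scheduler monitors the validation mean
foreground DSC (mode max) and multiplies the lr by 0.5 once `patience`
(default 10) consecutive validation checks have failed to improve on the
best value — i.e. a metric flat for 10 checks halves the lr on the 10th
stagnant check. Checkpointing keeps the weights of the best validation
epoch; checkpoints store the weights, batch-norm running statistics and a
JSON echo of the architecture config so they can be reloaded without any
other context.

Fold splitting is Monte-Carlo cross-validation: each of the k folds
reshuffles all identifiers independently (fold-specific seed) and takes
train/val/test = 138/4/30 for the nominal 172-sample dataset. Those sizes
consume the dataset exactly, which makes classically disjoint 5-fold test
sets impossible — independent reshuffling is the only protocol consistent
with them.

Augmentation (applied identically to volume and labels): in-sagittal-plane
rotation U(−10°, 10°) (trilinear for intensities, nearest for labels),
multiplicative contrast `exp(U(−0.2, 0.2))`, and an elastic deformation
from Gaussian-smoothed uniform noise (amplitude α = 2 voxels, smoothing
σ = 4; in-plane displacements only, since sagittal slices are thick).
These ranges are conventional choices exposed in the config; zero
magnitudes give the exact identity.

## Phantom generator

Phantoms emulate the statistical structure of the task, not anatomy: a
cranio-caudal stack of boxy bright "vertebrae" (superellipsoids, intensity
0.8) alternating with thin dimmer "discs" (0.5) on a 0.0 background, each
structure labeled 1..17 in top-to-bottom order, centers following a mild
sinusoidal curve (amplitude 5% of width, random phase). Per-sample
multiplicative contrast `exp(U(−0.2, 0.2))` produces intra-class variation
across samples; shared within-sample tissue intensities produce
inter-class similarity. i.i.d. Gaussian noise (sd 0.05) is added — no
Rician model, no bias field, no partial-volume effects, no anatomical
shape variation. Tests passing on phantoms therefore demonstrate that the
pipeline, optimization and metrics behave correctly and that the network
can exploit positional context; they do not demonstrate clinical
segmentation accuracy on real MRI, which additionally requires the
external 172-sample challenge dataset and full-scale training.

Defaults: 9 vertebrae + 8 discs (17 foreground classes) at 18×256×128 with
height fractions 0.06/0.02; the desk-scale profile uses 3 vertebrae +
2 discs (5 foreground classes) at 12×64×32 with fractions 0.14/0.05 so
structures keep realistic relative proportions at the smaller grid.

## Problem sizes used in the checks

The shape and protocol checks run the full-scale network (base 128,
18 classes, 18×256×128 input) forward once. Learning checks use the
reduced profile (base 32, 12×64×32, 5 foreground classes): an overfit
sanity run (2 phantoms, 200 update steps, constant lr — the plateau
scheduler is parked for this run because with one update per epoch 200
validation checks would otherwise decay the lr geometrically, which is an
artifact of the scaled-down epoch structure, not of the recipe) and a
10-train/3-test generalization run (4 epochs, full augmentation) compared
against the majority-class (all-background) baseline.

## Known limitations

- CPU-only and single-device; full-scale training (50 epochs × 138
  volumes) is far outside interactive time on numpy and is intended to be
  run only when the real dataset and patience (or a port of the model
  definition to a GPU framework) are available.
- Binary-CE loss and softmax probabilities are slightly mismatched in
  principle (the binary form treats classes as independent); both losses
  are provided, and the default follows the reference formulation.
- The MSD is not used for model selection and has no Hausdorff-95 or
  surface-Dice companions.
- NIfTI only; no DICOM ingestion, bias-field correction or registration.
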