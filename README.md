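# safnet

Multi-class 3D segmentation of vertebrae and intervertebral discs in
sagittal spine MRI with a **scene-aware fusion network** (SAFNet), packaged
with its full preprocessing chain, loss and metrics, a synthetic phantom
generator, and a five-fold cross-validation harness. It is aimed at medical
image-analysis researchers who want a transparent, dependency-light
reference implementation of this architecture family that runs end to end
on a workstation CPU.

## The problem

Spine parsing assigns every vertebral body (T, L, S levels) and every
intervertebral disc its own label — background plus 17 structures in the
nominal setting. Two properties make it hard: **inter-class similarity**
(adjacent structures look nearly identical within a scan, so position must
disambiguate them) and **intra-class variation** (the same structure varies
in contrast across scans).

## The model

The network reads a single-channel volume (B, 1, D, H, W) with axes
(sagittal slice, cranio-caudal, antero-posterior). Height and width are
halved at each encoder stage while the depth axis is never downsampled,
giving three 128-channel feature maps for an 18×256×128 input:

| level | shape (C×D×H×W) |
|---|---|
| low F_l | 128×18×64×32 |
| mid F_m | 128×18×32×16 |
| high F_h | 128×18×16×8 |

The stages on top of the encoder:

- **ASPP** over F_h: five branches — 1×1×1 reduction, three 3×3×3
  convolutions with in-plane dilation rates 6/12/18 (padding = rate, so
  `o = (i + 2p − k − (k−1)(d−1))/s + 1` preserves the size), and a
  global-pool branch — concatenated and projected back to C channels.
- **Self-attention**: position attention (row-softmaxed N×N affinity over
  the N = D·H·W flattened voxels, queries/keys at C/8 channels) followed by
  channel attention (C×C affinity). Both add their output through a scalar
  gate initialized to 0, so at initialization each module is an exact
  identity.
- **Multiscale fusion** on F_l and F_m: four cascaded C/4-channel branches
  with in-plane dilations 2/4/8/16; branch *i* adds branch *i−1*'s output
  before its dilated convolution, and the four outputs concatenate back to
  C channels at unchanged resolution.
- **Dimension splicing**: a channel gate
  `R_S = σ(GAP(F_h'))` (channel-attended) is broadcast-multiplied with the
  fused maps, `F_sh = R_SAM ⊙ F_l' ⊙ F_m'`; `[F_sh, F_l', F_m', F_h'']`
  concatenate at F_l resolution and a 1×1×1 convolution plus trilinear
  upsampling emits per-voxel class scores at input resolution.

Training minimizes the per-voxel-per-class binary cross-entropy mean

```
L = − Σ_{i,j,k,c} [ Y log P + (1−Y) log(1−P) ] / (H·W·D·C)
```

with Adam (lr 1e-3, weight decay 1e-4, batch 8, 50 epochs), a
reduce-on-plateau scheduler (mode max, factor 0.5, patience 10) on the
validation mean foreground Dice, and best-validation checkpointing.
Evaluation reports per-structure DSC (`2|A∩B|/(|A|+|B|)`) and mean surface
distance, as mean ± sample standard deviation.

Everything — including reverse-mode autodiff, 3D dilated convolution,
batch normalization, attention, Adam — is implemented on numpy in
`safnet.nn`, a compact autograd engine verified against finite differences.

## Worked example (CPU, ~1 minute)

```python
from safnet import (PhantomConfig, PreprocessSpec, SAFNet, SAFNetConfig,
                    TrainConfig, AugmentParams, FoldSplit, generate_dataset,
                    preprocess, train, evaluate)

pcfg = PhantomConfig.desk_scale()          # 12 x 64 x 32, 5 foreground classes
samples = generate_dataset(4, pcfg, master_seed=1)
spec = PreprocessSpec(target_shape=pcfg.shape, crop_width_fraction=1.0)
data = {s.sample_id: preprocess(s, spec) for s in samples}

model = SAFNet(SAFNetConfig.desk_scale(num_classes=pcfg.num_classes), seed=0)
cfg = TrainConfig(epochs=60, batch_size=2, seed=0, max_iters=60,
                  scheduler_patience=60,
                  augment=AugmentParams(rotation_deg=0, contrast_jitter=0,
                                        elastic_alpha=0))
fold = FoldSplit(0, train_ids=["phantom_000", "phantom_001"],
                 val_ids=["phantom_002"], test_ids=["phantom_003"])
history = train(model, fold, cfg, data)
print(f"final training loss: {history.train_loss[-1]:.4f}")
print(f"best validation DSC: {history.best_val:.4f} at epoch {history.best_epoch}")
table = evaluate(model, fold.test_ids, data)
print(table.per_class().to_string(index=False))
print("overall:", table.format_percent())
```

Output:

```
final training loss: 0.0256
best validation DSC: 0.7796 at epoch 59
 class_id class_name  n  dsc_mean  dsc_sd
        1    class_1  1  0.796131     0.0
        2    class_2  1  0.801527     0.0
        3    class_3  1  0.926661     0.0
        4    class_4  1  0.541205     0.0
        5    class_5  1  0.872581     0.0
overall: 78.76 ± 14.79 %
```

The loss falls from ln 2 toward zero as the network memorizes the two
training phantoms; the held-out phantom is segmented well for the thick
vertebrae (classes 1/3/5) and less well for the thin discs — class 4's
lower score reflects the position-only disambiguation between the two
identical-intensity discs, exactly the inter-class-similarity failure mode
the architecture targets. Longer training (see the acceptance tests)
pushes training Dice above 0.9.

A `safnet` console script exposes the same workflow from a shell:
`safnet generate`, `safnet train`, `safnet evaluate`, `safnet predict`,
`safnet crossval`, all driven by one YAML run config.

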