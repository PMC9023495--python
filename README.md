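# compressnet

A teacher-student network-compression toolkit for small image classifiers,
built around a three-step pipeline:

1. **Pre-train / fine-tune** — supervised cross-entropy training with SGD
   (momentum 0.9, weight decay 0.0005, batch 32, staged learning-rate
   ladders), optionally starting from a source-task pre-trained trunk with a
   fresh classifier head.
2. **Transfer** — the student is trained with an added hidden-vector matching
   penalty `λ‖H_S − H_L‖²` against a frozen teacher (λ = 1.0 by default),
   where `H` is the D-dimensional representation feeding the classifier head
   and both networks see the same augmented view of each image.
3. **Cut** — top-down layer-wise filter pruning: each filter of layer *t* is
   scored by the mean squared reconstruction error it induces in the next
   unchanged-size feature map, the `⌈C_t·α⌉` lowest-scoring filters are
   removed structurally (with their norm parameters, coupled depthwise
   channels and downstream input slices), and the cut network is retrained
   under the combined transfer objective before moving one layer down
   (α = 0.5 by default).

Augmentation follows the four-step train pipeline (random area scaling,
random aspect ratio at constant area, random crop, resize; then float
conversion to [0, 1] and channel-wise normalization) and the deterministic
resize + center-crop test pipeline. Evaluation reports per-category (macro)
top-k accuracy with mean ± std over repeated stratified 70/30 splits.

Everything runs on NumPy (im2col convolutions with hand-written backprop):
no deep-learning framework is required, which keeps the toolkit runnable on
a single CPU at desk scale. A deterministic synthetic image generator
(glyphs-on-textured-background classes with controllable count, noise,
inter-class similarity and geometric jitter) makes every stage testable
without any external dataset; real datasets in a folder-per-class PNG/JPEG
layout with a `manifest.tsv` are read through the same path.

## CLI

```bash
# generate a synthetic dataset (folder-per-class PNGs + manifest)
compressnet synth --out run/data --classes 10 --per-class 50 --seed 1

# train teacher and student
compressnet train --data run/data/dataset --arch desk_teacher --out run/teacher --seed 1
compressnet train --data run/data/dataset --arch desk_student --out run/student --seed 2

# hidden-vector transfer against the frozen teacher
compressnet transfer --student run/student/model.ckpt --teacher run/teacher/model.ckpt \
    --data run/data/dataset --lambda 1.0 --out run/xfer

# top-down cut at ratio 0.5 (writes ws_t.ckpt per layer, scores, report.json)
compressnet cut --student run/xfer/model.ckpt --teacher run/teacher/model.ckpt \
    --data run/data/dataset --alpha 0.5 --out run/cut

# macro top-k evaluation, and a cut-ratio sweep
compressnet evaluate --model run/cut/ws_final.ckpt --data run/data/dataset --topk 1,5 --out run/eval
compressnet sweep --student run/xfer/model.ckpt --teacher run/teacher/model.ckpt \
    --data run/data/dataset --holdout run/data/dataset --alphas 0.1:0.9:0.2 --out run/sweep
```

Every command accepts `--config cfg.yaml` (flags override the file) and
`--preset` (`paper-herb` carries the full-scale published recipe — batch 32,
momentum 0.9, weight decay 0.0005, λ = 1.0, α = 0.5 and the printed
learning-rate ladders; `desk` shrinks iteration counts for laptop runs).
Each run echoes its effective configuration and an append-only TSV log into
the output directory.

## Library layout

| module | contents |
| --- | --- |
| `compressnet.synthetic` | deterministic labeled-image generator, disk layout I/O |
| `compressnet.imaging` | train/test transforms, normalization helpers |
| `compressnet.network` | layer/network specs, NumPy forward/backward engine, checkpoints |
| `compressnet.training` | SGD with parameter groups, cross-entropy training, pre-train→fine-tune |
| `compressnet.distill` | hidden-vector transfer training |
| `compressnet.prune` | filter scoring, selection, structural removal, top-down compress loop |
| `compressnet.evaluation` | macro top-k, confusion matrices, repeated stratified splits |
| `compressnet.config` / `compressnet.cli` | YAML run configs, presets, CLI |

Reference architectures: desk-scale residual teacher and depthwise-separable
inverted-bottleneck student sharing one hidden dimension (so the transfer
loss applies directly), plus full-scale variants (the student variant has 17
prunable blocks).

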