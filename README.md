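# bsda

Feature-space semantic data augmentation for small image-classification
models. During training, each penultimate feature vector `a` is perturbed as

    a~ = a + I[a != 0] * d * m

where `d` is an elementwise Bernoulli(λ) mask over feature dimensions,
`m = σ ⊙ ε` is a reparameterized Gaussian draw whose per-dimension scale σ is
predicted from `a` by a small estimator network, and the indicator keeps
exactly-zero (post-activation) coordinates at zero. The estimator is trained
with a closed-form KL penalty toward a unit Gaussian plus an optional
reconstruction loss through a decoder that maps `m` back to `a`. The
combined objective is

    L = L_task(a) + α · (L_KL + L_recon + L_task(a~))

with α ramped linearly from 0 to its plateau (default 0.5) over the first
five epochs. Augmentation is a training-time regularizer only; inference is
the plain `classifier(feature_extractor(x))` forward pass.

Everything runs on CPU: the package ships a minimal NumPy reverse-mode
autodiff core (`bsda.nn`) with linear, batch-norm, GELU/ReLU and im2col
convolution layers plus AdamW, so no deep-learning framework is required.

## Layout

- `bsda.core` — direction sampling, σ estimation, reparameterized magnitude
  draws, masked augmentation, KL / reconstruction / total losses,
  `BSDAConfig`, `BSDAModule`.
- `bsda.harness` — `BSDAWrappedModel` (feature extractor + classifier with
  the module in between), reference backbones (small CNN, MLP), the
  training loop (`fit`) with warm-up and validation-AUC checkpointing,
  `predict`, checkpoint I/O.
- `bsda.synthetic` — desk-scale fixtures: ellipse-image datasets with a
  continuous per-class size attribute, and sparse non-negative feature
  datasets with known class means and a known label-preserving radius;
  packed `.npz` six-array export/import.
- `bsda.evaluation` — ACC / macro-OvR AUC (percent), the repeated-seed
  mean ± standard-error protocol, t-SNE export of original vs augmented
  features.
- `bsda.cli` — `train`, `ablate`, `sweep`, `visualize`, `make-data`
  subcommands; every run writes a resolved `config.yaml` snapshot for exact
  replay.

## CLI examples

```sh
# three-seed training run on the synthetic image set
bsda train --dataset synthetic-blobs --n 600 --size 32 \
     --bsda.lambda 0.5 --bsda.alpha-max 0.5 --seeds 0 1 2 --outdir runs/demo

# baseline (augmentation disabled)
bsda train --bsda.alpha-max 0 --outdir runs/baseline

# ablation table over the module variants
bsda ablate --variants base bsda no_indicator no_recon random_noise \
     --outdir runs/ablate

# (lambda, U) grid with improvement-over-baseline deltas
bsda sweep --lambda-grid 0 0.25 0.5 --u-grid 1 2 --outdir runs/sweep

# t-SNE of original vs augmented features from a trained checkpoint
bsda visualize --checkpoint runs/demo/checkpoint_seed0.npz --out tsne.csv

# write a packed six-array dataset file
bsda make-data --n 600 --size 32 --out blobs.npz
```

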