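# scafdl

Self-supervised, diffusion-based detection and **localization of
fracture-like anomalies** in single-channel radiograph crops — trained
entirely on healthy images.

The package is aimed at researchers working on reconstruction-based
anomaly detection for medical or industrial grayscale imagery who need
a fully reproducible, annotation-free pipeline: no fracture labels,
masks or pretrained weights are required at training time, and every
experiment in the repository runs on a built-in synthetic
phantom-radiograph generator.

## Method

Three stages are trained jointly from healthy images `N`:

1. **Pseudofracture synthesis.**  A random fracture-shaped polyline
   `P` (two border endpoints, 1–5 jittered interior points) is
   restricted to the bone foreground, `M = F ⊙ P`, filled with texture
   at opacity β, `A = β·T + (1−β)·N`, and composited,
   `S = M ⊙ A + (1−M) ⊙ N`.  Batches mix normal and pseudofracture
   samples 50/50 and pass through stochastic photometric/geometric
   augmentation.

2. **Guided diffusion reconstruction.**  A denoising U-Net with a
   transformer mid-block is trained on the standard forward process
   `x_t = √ᾱ_t·x0 + √(1−ᾱ_t)·ε`.  At inference, one time-step is taken
   from each of three schedule segments (short/medium/long);
   reconstructions from the medium and long steps are renoised to the
   short step and their deviation forms a guidance term

       Δ = w1·(x_{t_s|x̂0,m} − x_{t_s}) + w2·(x_{t_s|x̂0,l} − x_{t_s}),

   which corrects the predicted noise, ε_g = ε̂ − √(1−ᾱ_{t_s})·Δ,
   before a single-step inversion to the "healthy version" x̂0_guide of
   the input.

3. **Localization.**  An SE-augmented segmentation U-Net maps the
   (input, reconstruction) pair to a per-pixel saliency map in (0, 1),
   trained with smooth-L1 + class-weighted focal loss (α = 0.75, γ
   ramped 2 → 3.5) on the synthesis masks; the denoiser itself is
   trained by noise-prediction MSE on normal samples only.

Evaluation reports image AUROC (top-50 saliency mean as image score),
pixel AUROC, and the PRO-score — the normalized area under the
per-region-overlap curve for FPR ≤ 30 %.  The scientific background and
all numerical conventions are documented in [docs/methods.md](docs/methods.md).

The neural networks and optimizer run on a small reverse-mode autodiff
engine over numpy included in the package (`scafdl.nn`), verified
against finite differences in the test suite.

## Worked example

```bash
# 1. generate a phantom dataset (60 healthy train, 20+20 test, 32x32)
scafdl synthesize --out data --seed 0

# 2. train the desk profile (~5 min on one CPU core)
scafdl train --data data --out run --seed 1

# 3. evaluate, including the guidance-mode ablation
scafdl evaluate --data data --out report --checkpoint run/checkpoint.npz --ablation

# 4. localize a single image
scafdl localize --image data/test/fractured/0001.png \
                --checkpoint run/checkpoint.npz --out loc
```

A desk-scale run of steps 2–4 printed:

```
image AUROC 0.990  pixel AUROC 0.972  PRO-score 0.902
plain: image 0.988  pixel 0.975  PRO 0.909
   ng: image 0.990  pixel 0.973  PRO 0.902
  ing: image 0.990  pixel 0.972  PRO 0.902
image score: 0.4548
```

Reading the numbers: the trained model separates fractured from healthy
phantoms almost perfectly at the image level (image AUROC 0.990), ranks
fracture pixels above healthy pixels with pixel AUROC 0.972, and
recovers on average ~90 % of each fracture region at low false-positive
rates (PRO-score 0.902).  The ablation rows compare plain one-step
reconstruction, single-step guidance (`w2 = 0`) and full multi-step
guidance; on the easy 32×32 phantom task the three modes perform
within noise of each other.  The `localize` command writes a binary
mask, a blue-to-red heatmap overlay, and the image score (0.45 here —
well above the ~0.02–0.1 scores of healthy phantoms).

`evaluate` writes `report.json`, per-image `scores.csv`, and both
`roc_curve.csv` and `pro_curve.csv` under `--out`.

## Configuration

Two profiles share one code path: `desk` (default; 32×32, T = 200,
narrow networks — minutes on a CPU) and `paper` (128×128, T = 1000,
transformer depth 12, batch 16, lr 1e−5, 1500 epochs — configuration
only).  Any key can be overridden via a YAML file passed with
`--config`, e.g.:

```yaml
profile: desk
seed: 7
guidance: {w1: 0.5, w2: 0.5, triple: [60, 100, 140], mode: random}
loss: {alpha: 0.75, gamma_mask: 1.0}
train: {steps: 2000, lr: 0.001}
```

Unknown keys are rejected.  Every run directory contains the full
config snapshot, the seed and a JSON-lines training log.
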