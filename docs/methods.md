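# Methods

`scafdl` implements a three-stage, reconstruction-based pipeline for
detecting and localizing fracture-like anomalies in single-channel
radiograph crops, trained without any fracture annotations.  Training
uses healthy images only; anomaly labels come from self-supervised
pseudofracture synthesis.

## Stage I — pseudofracture synthesis

A healthy image `N` with bone-foreground mask `F` is turned into a
training pair `(S, M)`:

1. a fracture-shaped polyline `P` is drawn between two points on
   opposite halves of the image border with `k ~ U{1..5}` jittered
   interior way-points, rasterized with Bresenham segments and dilated
   to a configurable thickness (default 1 px, giving 2–3 px lines at
   desk scale);
2. `P` receives aggressive geometric jitter (rotation ±90°, shear
   0–40°, translation ±50 %, scale 50–100 %) and is restricted to the
   bone, `M = F ⊙ P`;
3. texture from a bank of band-limited-noise ("bone-overlap-like") and
   near-uniform dark ("background-like") patches is blended at opacity
   `β ~ U[0.5, 1.0]`: `A = β·T + (1−β)·N`;
4. the pair is composited: `S = M ⊙ A + (1−M) ⊙ N`.

Outside `M`, `S` equals `N` exactly; the label is `y = [M ≠ ∅]`.
Batches mix normal and pseudofracture samples 50/50.  During training,
three augmentation ops drawn without replacement from a merged pool
(gamma `[0.5, 2]`, brightness gain `[0.8, 1.2]` ± 30/255, solarize
threshold `[32, 128]/255`, autocontrast, histogram equalization, whole-
image rotation ±45°) are applied per sample; geometric ops move image
and mask together (nearest-neighbour for the mask).  Hue/saturation
ops are omitted: inputs are single-channel.

Foreground segmentation is pluggable: `oracle` (the generator's exact
mask) or `threshold` (Otsu + largest connected component + hole fill,
IoU ≥ 0.90 against the oracle on phantoms).  A learned segmentation
model can be substituted behind the same interface.

## Stage II — diffusion reconstruction with multi-time-step guidance

The forward process is the standard variance-preserving diffusion

    x_t = √ᾱ_t·x0 + √(1−ᾱ_t)·ε,   ᾱ_t = ∏_{s≤t}(1−β_s),  ᾱ_0 ≡ 1,

with a linear β schedule (1e−4 → 0.02).  A U-Net `ε_θ(x_t, t)` predicts
the injected noise; its bottleneck is a stack of transformer encoder
layers (multi-head self-attention, residual connections, layer norm,
additive sinusoidal time embedding) operating on the flattened spatial
grid.  One-step inversion is

    x̂0 = (x_t − √(1−ᾱ_t)·ε̂) / √ᾱ_t ,

the exact algebraic inverse of the forward step, which the tests verify
to 1e−6 at every t.

**Guided reconstruction.**  The schedule is partitioned into short /
medium / long segments (fractions 0.3/0.5/0.7 of T; at T = 1000 that is
(0,300], (300,500], (500,700]).  One step is sampled (or fixed) per
segment, `t_s < t_m < t_l`.  The input is diffused to all three steps
with one shared noise draw ε; reconstructions x̂0_m and x̂0_l obtained
at the medium/long steps are renoised to t_s *with the same ε* and
their deviation from x_{t_s} forms the guidance term

    Δ = w1·(x_{t_s|x̂0,m} − x_{t_s}) + w2·(x_{t_s|x̂0,l} − x_{t_s}),

which corrects the predicted noise, ε_g = ε̂_θ(x_{t_s}, t_s) −
√(1−ᾱ_{t_s})·Δ, before a final one-step inversion (clipped to [0,1]).
Defaults w1 = w2 = 0.5.

Reusing the forward noise draw in the renoising step makes Δ
deterministic given ε and admits an exact oracle: for a denoiser that
always points at a target x* (ε̂ = (x_t − √ᾱ_t·x*)/√(1−ᾱ_t)),
substituting the four equations above collapses to

    x0_guide = x* + (w1+w2)·(1−ᾱ_{t_s})·(x* − x_in).

(The √ᾱ_{t_s} factors cancel in the final division.)  The test suite
asserts pipeline-vs-closed-form agreement to 1e−6 over a grid of
(t_s, w1, w2), the w1=w2=0 reduction to unguided one-step
reconstruction, and the fixed point x0_guide = x* at x_in = x*.

## Stage III — localization and losses

The localizer is an encoder–decoder segmentation U-Net with skip
connections; a squeeze-and-excitation block (reduction ratio 16,
hidden width floored at 4 for narrow profiles) closes each encoder
stage to damp background/overlap clutter.  It takes (input image,
guided reconstruction) stacked on the channel axis and emits a saliency
map through a terminal sigmoid.

Losses (`y` the per-sample label, `M`/`M̂` mask and saliency):

* noise loss — `L_noise = (1/3)·(1−y)·Σ_{t∈{t_s,t_m,t_l}} mean‖ε − ε̂_t‖²`;
  pseudofracture samples are gated out, so the denoiser learns the
  healthy-image distribution only;
* mask loss — `L_mask = SmoothL1(M, M̂) + γ_mask·Focal(M, M̂)` with
  `γ_mask = 1`, focal class weight α = 0.75 on fracture pixels, and the
  focusing exponent γ ramped linearly from 2 to 3.5 across the run
  (per-step granularity); saliency is clamped by 1e−6 before the log;
* `L_total = L_noise + L_mask`.

By default the reconstruction fed to the localizer is detached, so
`L_mask` trains the localizer alone and the denoiser is shaped purely
by `L_noise`; a `detach_reconstruction` flag exposes the joint
alternative, and a finite-difference test verifies the detachment
actually blocks gradient flow.

Normal samples participate in `L_mask` with empty target masks.

## Metrics

* image score — mean of the top-K (default 50) saliency values;
* image/pixel AUROC — midrank tie convention (pixels pooled across all
  test images; normal images contribute all-zero masks);
* PRO curve — thresholds swept over the ≤256-level subsampled set of
  unique saliency values plus {0, 1}, binarized with strict `>`;
  PRO = |P∩G|/|G| averaged over fractured images only, FPR pooled over
  the non-anomalous pixels of all images; the PRO-score is the
  trapezoidal area under the upper envelope of PRO-vs-FPR restricted to
  FPR ≤ 0.3, normalized by the cap (flat extension if the sweep never
  reaches the cap, linear interpolation if it crosses it).

Each metric is tested against a brute-force oracle (exhaustive pairwise
comparisons for AUROC; a per-pixel loop for every PRO point).

## The phantom generator

Clinical wrist radiographs are not redistributable, so the package
ships a seeded phantom generator that reproduces the statistical
features the pipeline depends on: a bright, connected, smoothly shaded
super-ellipse "bone" (15–60 % of pixels, random size/orientation/
squareness) with a Gaussian-smoothed multiplicative density field;
a dark background with smooth clutter, 1–3 faint elongated distractor
blobs (standing in for neighbouring-bone interference) and mild pixel
noise; and true-fracture test cases — thin dark polylines strictly
inside the bone at three severities (`subtle`, `line`, `displaced`,
proxies for occult / nondisplaced / displaced patterns; ~18 %, 45 %
and 60 % mean intensity drop, the last with a wider gap).  Masks mark
exactly the altered pixels.  Images are 8-bit PNG on disk, float [0,1]
in memory; all file-based tests allow 1/255 quantization.

What phantoms do *not* model: real anatomy, projection geometry,
scanner noise spectra, soft tissue, or the lateral-view bone-overlap
texture statistics of clinical fracture fillings (the texture bank is
an explicit stand-in).  Passing tests therefore demonstrate that the
machinery is correct and that the method separates thin dark anomalies
from healthy structure under clutter — not clinical performance.

## Scale profiles and numerical choices

All networks run on a small in-repo reverse-mode autodiff engine over
numpy (float32, im2col convolutions, Adam); gradients are verified
against central finite differences for every primitive and both
architectures.

* `desk` profile (default; used by the tests and the acceptance
  script): 32×32 images, T = 200 with segments (0,60]/(60,100]/
  (100,140], denoiser width 8 with transformer depth 2, localizer width
  16 with 3 SE stages, batch 8 (≈4 normal + 4 pseudofracture), Adam at
  1e−3 for 1000 steps.  The widths and step count were profiled so a
  full 3-seed training comparison completes in minutes on one CPU core;
  on held-out phantoms this configuration reaches image AUROC ≈ 0.95–
  0.99 and PRO-score ≈ 0.85–0.90 per seed (the test suite asserts the
  looser bars ≥ 0.90 / ≥ 0.50 on the median of three seeds).
* `paper` profile (configuration only): 128×128 images, T = 1000 with
  the 300/500/700 fixed triple, transformer depth 12, batch 16, Adam at
  1e−5 for 1500 epochs.

Other choices: time indexing is 1-based with ᾱ_0 ≡ 1 and one-step
inversion rejects t = 0; the time-step triple is resampled per training
batch (uniformly within each segment) and fixed to the segment upper
bounds at inference; per-image noise in batch reconstruction is derived
from a CRC of the image content, making results order-equivariant;
ε̂ at t_s is computed once and reused for the guided noise and the
final inversion; if an aggressively transformed pseudofracture shape
misses the foreground it is redrawn, falling back to untransformed
border-spanning shapes.

## Known limitations

* The engine is single-threaded numpy; the paper-scale profile is
  supported but impractically slow without a compiled framework.
* The phantom foreground is convex-ish and centered; the `threshold`
  segmentation backend has not been exercised on multi-bone layouts.
* PRO's FPR pools pixels across images (per-image averaging is a
  plausible alternative reading); normal images are excluded from PRO
  but included in the pooled FPR.
* `displaced` severity is rendered as a wider, darker gap rather than a
  true rigid displacement of one fragment.
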