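# Methods

## Problem setting

Label-free photoacoustic histology (PAH) images unstained tissue with
ultraviolet excitation; DNA/RNA absorption renders nuclei bright on a dark
background. The package converts such tiles into H&E-style images, segments
and measures nuclei, and classifies tiles as cancerous or noncancerous, with
the three stages sharing outputs: virtually stained tiles feed segmentation
and classification, and morphometric features feed classification.

## Virtual staining (E-CUT)

An unpaired image-to-image translation model with a single generator and a
single patch discriminator.

**Generator.** Fully convolutional: a 7×7 stem, two stride-2 downsampling
convolutions, nine residual blocks (3×3 convolutions, padding-preserving,
additive skip), two nearest-neighbour-upsample + convolution stages, a 7×7
output convolution with tanh. Instance normalization throughout. Output
spatial size always equals input size; `base_width` scales all channel
widths (64 at full scale, 8 in the desk profile). Network tensors live in
[−1, 1]; images are 8-bit at the interface.

**Discriminator.** PatchGAN: stride-2 4×4 convolutions (3 of them) followed
by two stride-1 4×4 convolutions, leaky-ReLU 0.2, instance norm on middle
layers. Every output element sees a 70×70 input patch; the scalar score is
the map mean. Fully convolutional, so any input size ≥ the tile sizes used
here works.

**Objective.** `l = l_adv + (l_NCE(X) + l_NCE(Y))/2 + l_sal`, all weights 1
by default and configurable:

* *Adversarial*: least-squares form — discriminator
  `mean((D(y)−1)² + D(G(x))²)/2`, generator `mean((D(G(x))−1)²)`.
* *PatchNCE*: features are tapped at five encoder depths (the input, the
  stem, both downsampling stages, and the middle residual block), projected
  by per-depth 2-layer MLPs to a shared embedding, L2-normalized, and
  compared by InfoNCE at temperature 0.07. The positives are the
  same-location patches of the input image; the negatives are the other
  sampled locations of that same image. 256 locations per depth at full
  scale (64 in the desk profile). The `Y` term applies the same construction
  to the identity pass `G(y)`, penalizing gratuitous changes to
  already-target-domain images.
* *Saliency*: `L1(m(x̄, 90), m(gray(G(x)), 170))` with
  `m(v, t) = 1 − sigmoid((v − t)·100)` computed on the 0–255 intensity scale
  (the module rescales the generator's tanh output before masking). With
  slope 100 on 8-bit data the mask is a hard indicator except in a
  ~0.1-level band around the threshold, yet remains differentiable, so it
  can serve simultaneously as a loss and as an explainability overlay. The
  thresholds (90 source / 170 target grayscale) are fixed constants, not
  learned; both are configurable. Border pixels are included in the loss.

**Training.** Adam (β₁ = 0.5, β₂ = 0.999), lr 2·10⁻⁴ constant for the first
half of training then linearly decayed to exactly 0, batch 1, horizontal
flips drawn independently per domain (pairing is undefined in unpaired
training). Defaults: 400 epochs. Loss-term means are recorded per epoch;
saliency-mask and attribution snapshots can be written per epoch (per step
behind a flag, which is impractically verbose). A NaN guard aborts with the
failing epoch. Checkpoints are self-describing `.npz` bundles (architecture
metadata + parameters) and reload to bitwise-identical inference.

**Attribution.** Integrated gradients of the mean discriminator score,
50-step Riemann approximation from a zero (black) baseline:
`IG_i = (x_i − b_i) · mean_k ∂F/∂x_i |_{b + (k/steps)(x−b)}`. Exact for
linear scorers. One caveat discovered while validating the completeness
axiom (attributions summing to `F(x) − F(baseline)`): instance normalization
makes the path integrand pathological from a black baseline — the normalized
activations are almost scale-invariant until the path point is nearly black,
so the gradient mass concentrates in a thin layer near α ≈ 0 that a 50-step
(or even 400-step) quadrature cannot resolve; residuals of 10–40% were
measured on the instance-norm patch discriminator with verified-correct
gradients. Completeness is therefore checked on a small normalization-free
discriminator (piecewise-linear score, residual ≈ 0.3–0.5% at 50 steps);
attribution maps for instance-norm discriminators remain useful
qualitatively but their sums should not be read as exact score differences.

## Segmentation and morphometry

**U-Net.** Four contraction and four expansion levels with skip
connections; each level is two 3×3 convolutions with instance norm and ReLU;
downsampling by 2×2 average pooling, upsampling by nearest-neighbour + 3×3
convolution; 1-channel logit output at input resolution. 1-channel inputs
are stacked to 3 channels at call time.

**Loss.** Binary cross-entropy plus (1 − Dice), equally weighted, Dice
smoothing ε = 1. Training uses the numerically stable logits form; the
public `bce_dice_loss` operates on probability maps.

**Training.** Adam (β₁ = 0.9, β₂ = 0.999), lr 10⁻⁴, batch 64, up to 300
epochs with early stopping on validation loss (patience 20) and
horizontal/vertical flip augmentation; the best-validation parameters are
restored. Inference optionally averages probability maps over the four axis
flips (test-time augmentation) before thresholding at 0.5.

**Features.** Nuclei are 8-connected components of the binary mask with at
least `min_area = 10` px (a speckle guard; count is monotonically
non-increasing in it). Per
tile: mean component area (px²), component count, and mean intercellular
distance between nucleus centres, where a centre is the centre of the
component's minimum enclosing circle (Welzl's algorithm — chosen for
fidelity to the named contour tooling rather than centroids). "Mean
intercellular distance" is ambiguous; the default is the mean
nearest-neighbour distance (matching the density intuition), with the
all-pairs mean behind a flag. Degenerate tiles yield NaN sentinels: area
undefined at count 0, distance undefined below count 2. Outlier fencing
retains values in [Q1 − 1.5·IQR, Q3 + 1.5·IQR] with linear-interpolation
quartiles; feature tables report class summaries both fenced and unfenced,
and the features fed to the classifier are unfenced per-tile values.

## Fusion classification (StepFF)

Three branches produce 16-dim deep feature vectors (DFVs): a 1-channel
ResNet-18-style backbone for the label-free tile, a 3-channel one for the
stained tile (each: 3×3 stem, four stages of two basic blocks, global
average pooling to an 8·width embedding — 512 at the classic width — then a
linear map to 16), and a linear map from the morphometric features (3 per
image source, z-normalized with mean/sd estimated on the training fold
only; constant features get sd 1). The DFVs are concatenated in the fixed
order (PAH ‖ VHE ‖ SEG) and a final linear layer yields two logits with
softmax. Branches and head train jointly end-to-end (per-branch freezing was
considered and rejected as an unstated complication).

Focal loss `−α(1−p_t)^γ log p_t` with γ = 2, α = 0.5 (canonical γ; neutral α
since the synthetic datasets are balanced). Adam lr 10⁻⁴, β = (0.9, 0.999),
batch 32, up to 1000 epochs with early stopping on a validation split carved
from the training portion. Evaluation is stratified 5-fold cross-validation;
fold assignment accepts a `groups` argument so tiles that share pixels via
overlapping crops are co-assigned to one fold. Metrics: accuracy, F1,
precision, recall, with the cancerous class positive and zero-denominator
cases reported as 0 with a warning. Ablations (single or dual modality)
reuse the same machinery with a shorter fused vector.

The whole-slide cancer-probability map renders each tile as the linear blend
between blue (0, 0, 255) at p = 0 and purple (128, 0, 128) at p = 1 (the
colour names are fixed; these RGB endpoints are the package's choice) and
merges tiles with the overlap-averaging stitcher.

Rater agreement: Cohen's κ = (p_o − p_e)/(1 − p_e) for two raters (κ ≡ 1
when both raters are constant and equal, where the formula is 0/0), Fleiss'
κ as the default for three or more, with pairwise Cohen's also reported —
the variant for multiple raters is otherwise unspecified.

## Tiling and intensity conventions

Coordinates are 0-based and row-major; tile windows are half-open. Tiles are
512×512 at 50% overlap by default (stride = tile·(1−overlap)); images are
padded with a constant (255, the white background of the inverted/stained
domain; configurable) to the next stride multiple, and the padding is
recorded and cropped on stitching. Stitching sums tile values per pixel in
float64, divides by the cover count, and rounds half away from zero to
8-bit — this makes crop→stitch the identity on integer images (the rounding
and edge policies are declared conventions; the underlying description fixes
neither). Intensity inversion is `v → 255 − v`; ×2 downsampling is 2×2 area
averaging with edge replication on odd extents; grayscale conversion for
saliency is the unweighted channel mean. Tissue coverage is the fraction of
pixels deviating from a background level by more than a tolerance (any
channel); the exclusion rule drops tiles under 20% coverage. Raw-image
conditioning (percentile contrast stretch, median filter, background
subtraction) exists but is off by default — the synthetic data does not need
it and no parameters are published for the real acquisition chain.

## Synthetic data: what it emulates and what it does not

The generator is the package's stand-in for non-public human-liver data.
A scene is a set of nucleus disks placed by rejection sampling with minimum
centre separation 0.8·(r_i + r_j) — mild overlap mimics dense cancerous
fields and exercises contour merging. Defaults (per 10⁴ px²): noncancerous
density 6, radius 5 ± 1 px; cancerous density 15, radius 6 ± 1.2 px, minimum
radius 3 px. So cancerous fields carry ≈2.5× the nucleus count, shorter
nearest-neighbour distances, and slightly larger nuclei — the class
contrasts the real study reports. Renders: label-free (background 20,
nucleus 200, anti-aliased edges, Gaussian noise sd 8), H&E-style (background
(250, 250, 250), cytoplasm halo (230, 180, 200) at 2.2× the nucleus radius,
nucleus (120, 60, 160)), and the exact lattice mask (pixel inside iff centre
distance ≤ radius). The 8-bit levels are chosen so the saliency sigmoid
saturates exactly as real 8-bit data would. Paired renders of one scene
exist only so tests can check geometry preservation; translation training
remains unpaired.

Not emulated: physically realistic photoacoustic image formation, stain
vector colour models, nuclear pleomorphism and texture, stromal structures,
section registration between adjacent slides. Passing tests therefore
demonstrate that the machinery is correct and that the method recovers
constructed class signals; they say nothing about accuracy on real tissue,
and the published clinical accuracies are expressly out of reach without the
clinical data and full-scale training. Feature units are pixels throughout
(no physical pixel-size calibration is available).

## Desk-scale profile and problem sizes

Full-scale defaults (512-px tiles, width-64 networks, 400/300/1000 epochs)
are the shipped configuration. Tests, examples and the acceptance script use
the desk profile — the package's chosen CPU-sized conditions:

* staining: 16 tiles per domain at 64 px, width 8, 30 epochs, 64 patches;
* segmentation: width 8 at 64 px; batch 1–2 on the tiny fixtures so the
  optimizer takes enough steps at the fixed lr 10⁻⁴ (an 8-tile full batch
  would yield one step per epoch);
* classification: width 2, inputs are 128-px scenes area-downsampled twice
  to 32 px, up to 120 epochs with patience 12 — 128-px scenes carry the
  ~10 vs ~25 nucleus contrast that survives downsampling;
* smoke pipeline: 8 tiles per class at 64 px, 6 staining epochs.

## Numerical and engineering choices

* All trainable models run on the package's numpy reverse-mode autograd
  engine (`pahisto.nn`): float32 tensors, im2col convolutions backed by
  BLAS matmul, Adam, deterministic throughout — fixed seeds reproduce
  training histories bitwise on a given platform.
* Normalization: instance norm in the generator, discriminator and U-Net
  (batch-size independent, no running state); batch norm in the
  classification backbones, matching their classic design — per-tile mean
  intensity is itself discriminative there and instance norm would erase
  it. Batch-norm inference uses stored running statistics, so predictions
  are independent of batch composition.
* Zero padding in all convolutions; generator upsampling is
  nearest-neighbour + convolution (avoids checkerboard artifacts of strided
  transpose convolutions).
* FID uses the unbiased covariance estimator and symmetric eigendecomposition
  square roots with negative-eigenvalue clipping
  (tr((Σ_a Σ_b)^{1/2}) = tr((Σ_a^{1/2} Σ_b Σ_a^{1/2})^{1/2})) for stability
  at small n. KID is the block-averaged unbiased MMD² with kernel
  (x·y/d + 1)³. The bundled feature extractor is a fixed-seed random
  convolutional projection (16 5×5 filters; mean + sd of rectified
  responses) requiring no downloaded weights; numbers comparable to
  published Inception-based scores require injecting the standard pretrained
  Inception extractor, which is not bundled.
* The pipeline derives per-stage seeds from the global seed through a fixed
  SeedSequence construction, so stages are independently reproducible, and
  stamps every artifact with the config hash.

## Known limitations

* Desk-scale generation quality is far from FID-competitive; the tiny GAN
  runs demonstrate optimization behaviour and saliency preservation, not
  staining fidelity.
* Dense cancerous fields merge under the mask representation; the contour
  stage counts merged clusters as single nuclei (no watershed splitting by
  design), which compresses the count contrast at high density.
* The engine is CPU-bound numpy: roughly one to two orders of magnitude
  slower than a GPU framework, which is why shipped test conditions are
  desk-scale.
* Cross-validation operates inside the training portion of any
  train/test split; nesting beyond that is not implemented.
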