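# Methods

## Problem setting

Minirhizotron tubes produce large (typically 2271 × 2550 px) RGB scans of
plant roots growing against soil. Root phenotyping pipelines need a binary
segmentation of those scans — root vs. background — and the task is hard
for two reasons: roots are thin, elongated, low-contrast structures whose
color overlaps the soil's, and field soil is full of distractors (stones,
worms, soil cracks, residual plastic film) that look locally root-like.
`rootseg` implements a segmentation network designed for exactly this
regime, together with the data pipeline, training engine, metrics and a
synthetic scene generator so the whole system can be exercised and tested
without access to field data.

## Model

### Backbone: HRNetV2

The backbone maintains four parallel subnetworks at 1/4, 1/8, 1/16 and
1/32 of input resolution with C, 2C, 4C and 8C channels (C = 48 in the
full-scale configuration, so the deepest branch is 384 wide). Stage 1 is
four ResNet-50-style bottleneck units (width 64, 4× expansion); stages
2–4 contain 1, 4 and 3 exchange blocks. Each exchange block runs four
two-conv residual units per live branch and ends in one *exchange unit*
that fuses every branch into every other (stride-2 3×3 convolutions
downward, 1×1 conv + bilinear upsampling upward, summed then ReLU) — 8
exchange units in the default layout. The final representation
concatenates all four branches at 1/4 resolution: 15C channels (720 for
W48). High-resolution streams are preserved end-to-end, which is the
property that matters for thin roots.

Details the architecture family leaves open were fixed as follows:

- **Stem**: two stride-2 3×3 conv+BN+ReLU layers (total stride 4).
- **Cross-resolution fusion**: bilinear upsampling for the
  low-to-high paths; the last conv of each high-to-low chain carries BN
  without ReLU.
- **Final concatenation**: bilinear upsampling of the three lower
  branches.
- **Initialization**: He-normal (fan-out) for convolutions, BN γ=1/β=0,
  and *zero-initialized closing BN scale* in every residual unit so a
  fresh unit starts as an identity map. The zero-init choice matters in
  practice: it keeps the 30-odd-unit backbone optimizable from random
  initialization within few iterations, and the desk-scale overfit run
  depends on it. No pretrained weights are assumed; a checkpoint-loading
  hook (`rootseg.nn.load_state`) exists for weights in the package's own
  `.npz` format.
- **Input normalization**: images enter as float32 in [0, 1]
  (`normalize_image`). The first BN layer absorbs the affine choice, so
  mean/std standardization was deliberately not added.

### OCR head

Pixel representations `x` (a 3×3 conv+BN+ReLU projection of the 15C
concat to 512 channels) are augmented with object-contextual
information computed against the two classes:

- soft object regions: the auxiliary FCN head (3×3 conv+BN+ReLU then
  1×1 conv, operating on the raw backbone concat) produces coarse
  logits; a **softmax over the spatial dimension per class** turns each
  class map into weights m̃ that sum to 1, so the region representation
  f_k = Σᵢ m̃_ki xᵢ is a convex combination of pixel vectors. A
  per-pixel softmax would be the other defensible reading of
  "normalized degree"; the spatial form is the canonical OCR behavior
  and is what the algebraic tests pin down.
- pixel–region relation: w_ik = softmax_k φ(xᵢ)ᵀψ(f_k) with φ, ψ 1×1
  conv+BN+ReLU transforms to 256 channels. Dot products are *not*
  scaled by 1/√d — the relation is used exactly as written.
- contextual representation: y_i = ρ(Σ_k w_ik δ(f_k)), δ and ρ again
  1×1 conv+BN+ReLU (256 channels).
- fusion: z_i = g([xᵢ; yᵢ]) with g a 1×1 conv+BN+ReLU to 512 channels,
  followed by a 1×1 classifier and bilinear upsampling (×4) to input
  scale.

Transform widths (512/256/256/512) follow the canonical OCR
configuration and are config-exposed.

### Attention (GAM)

The improved variant inserts a Global Attention Mechanism immediately
after the pixel representations. Channel submodule: permute so channels
trail, a two-layer MLP C → C/r → C shared across positions (ReLU
between layers), inverse permute, sigmoid → full-shape gate M_C;
F₂ = M_C ⊗ F₁. Spatial submodule: 7×7 conv to C/r (+BN+ReLU), 7×7 conv
back to C (+BN), sigmoid → M_S; F₃ = M_S ⊗ F₂. Both gates are strictly
inside (0, 1), so the module only attenuates: |F₃| ≤ |F₁| elementwise,
and clamping both gates to 1 recovers the attention-free baseline
bit-for-bit (the ablation path, `gam_enabled: false`).

The reduction ratio r is not fixed by the architecture description;
the default r = 4 follows the original attention module and is
config-exposed. The optimized representations feed *all* downstream
consumers — region representations, relation, context, and the final
fusion. A flag (`fuse_original`) restores raw-x fusion for comparison,
since the narrower reading (only the three context computations see the
optimized x) is also defensible.

## Training

Objective: pixel-wise cross-entropy on both outputs,
`0.4 · CE(aux) + 1.0 · CE(final)`. Probabilities come from a 2-channel
softmax, which for two classes equals the binary cross-entropy on the
root probability; probabilities are clamped to [ε, 1−ε], ε = 1e-7, for
log stability (gradient is masked outside the clamp interval).

Schedule: polynomial decay with an additive floor,

    lr(t) = (lr0 − lr_min) · (1 − t/T)^p + lr_min

with lr0 = 0.01, p = 0.9, lr_min = 1e-4, T = 40 000 in the reference
configuration. This form is chosen because it hits both documented
endpoints exactly; a multiplicative floor (max of decay and lr_min)
would match the endpoints but kink mid-schedule.

Optimizer: SGD with classical momentum (v ← μv + g + λθ; θ ← θ − lr·v),
μ = 0.9, weight decay λ = 5e-4 applied to all parameters including BN
(whether the original training exempted BN is unknown; exempting it
made no observable difference at desk scale). Batch size 4; each
iteration draws images uniformly with replacement and takes one uniform
random 512 × 512 crop per image (reflect-padding images smaller than
the crop). Checkpoints every 500 iterations are scored by whole-image
validation IoU via tiled inference; the best checkpoint is the highest
IoU, ties resolved toward the later iteration.

## Inference on full-size scans

`tiled_predict` slides a `tile` window (default 512) with overlap
(default 256, i.e. stride 256), averages final logits over all windows
covering a pixel, and takes the argmax. The image is reflect-padded to
alignment; the padding is cropped away before the argmax is returned.
The 256-pixel overlap was chosen to suppress seam artifacts; images no
larger than one tile bypass padding entirely when their dims are
divisible by 32, making the single-tile path bit-identical to a
whole-image forward.

## Evaluation

Confusion counts (root = positive class) are pooled globally over all
pixels of all images, then accuracy, recall, precision, F1 and IoU are
computed once; `per_image_mean` switches to averaging per-image values,
since published dataset-level figures could have been produced either
way. Degenerate 0/0 ratios evaluate to 1.0 (an empty prediction of an
empty image is perfect). Reports round to 4 decimals. The identity
IoU = F1/(2−F1) holds for any counts with a nonzero union and is used
as a cross-check in the test suite.

## Data pipeline

Annotations: LabelMe polygon JSON (shapes labeled `root`, filled and
unioned; other labels skipped with a warning) or paletted PNG masks,
red (255,0,0) = root, black = background, round-trip safe.

Augmentation (×5 per original): luminance ×1.2 and ×0.8, isometric
scaling ×1.2 and ×0.8 (bilinear image / nearest mask, canvas dims
change with the scale), and salt-and-pepper noise at density 0.02.
The magnitudes are conventional mild values — the original study names
the five transforms but not their strengths — and are config-exposed.
Photometric variants keep the mask bit-identical.

Splitting: 92 originals × 6 = 552 samples are split 6:2:2 as
⌊0.6·G⌋ whole groups (G = source-image count, shuffled by seed) into
training and the remaining samples halved into validation/test (odd
remainder to validation). This reproduces the canonical 330/111/111
partition exactly — naive per-sample 6:2:2 of 552 would give
331.2/110.4/110.4 — and guarantees augmented copies of one source image
never straddle training and evaluation.

## Synthetic scenes

The generator emulates what the segmenter must cope with: Gaussian-blurred
multi-octave soil texture; roots as random-walk polylines (downward drift,
angular jitter, tapering width, occasional lateral branch) rendered as
anti-aliased strokes whose tone sits a configurable contrast above the
soil band; and the four distractor families — bright ellipses (stones),
thin dark polylines (cracks), large bright blurred polygons (plastic
film), short thick bright strokes (worms). The mask is the root stroke
alpha thresholded at 0.5; distractors never enter the mask. Texture,
distractors and roots draw from three independent PCG64 streams spawned
from the scene seed, so the ground truth is invariant to the distractor
configuration and every scene is bit-reproducible from (spec, seed).

What the generator does **not** emulate: true soil color statistics,
lighting gradients and vignetting of tube scanners, root hairs and
decayed roots, occlusion by condensation, and the temporal structure of
repeated scans. Passing tests on synthetic scenes therefore demonstrate
that the architecture, losses, pipeline and metrics are wired correctly
and that the network can learn curvilinear structure against textured
clutter — they say nothing quantitative about accuracy on real
minirhizotron imagery.

## Desk-scale configuration (`presets.smoke`)

The reference configuration (W48 backbone, 512-wide head, 512 crops,
40k iterations) is far beyond a single CPU. The smoke preset scales
every axis down: backbone width 8 with stage-1 bottleneck width 16,
head widths 32/16/16/32, 96 × 96 scenes, batch 8, 300 iterations,
checkpoint every 100. The batch is twice the reference size because
with only a few hundred steps the BN statistics and gradient noise of
small batches dominate run-to-run variance; doubling the batch costs
seconds here and stabilizes the short run. Scenes for the overfit check use wide
(8–16 px), higher-contrast (0.45) roots with mild texture: at the
backbone's 1/4 output stride, a thin-root scene caps the achievable
IoU well below the check's 0.8 bar regardless of model quality (the
ceiling of a stride-4 oracle on 2–6 px roots is ≈ 0.84), so the
fixture uses roots the resolution can actually represent
(ceiling ≈ 0.94). The schedule is hotter than the reference
(lr0 = 0.1, lr_min = 0.001) because a 300-iteration budget from random
initialization needs larger steps; the polynomial form and optimizer
are unchanged.

## Numerical choices

- float32 throughout the network; losses accumulated in float64 where
  computed outside the graph.
- BN: ε = 1e-5, running-stat momentum 0.1, biased variance for
  normalization.
- Softmax/log-softmax: max-shifted; sigmoid exponentiates only the
  non-positive branch.
- Bilinear resizing uses half-pixel centers (align_corners = false
  convention) implemented as separable row/column operators, so its
  adjoint (the gradient) is exact.
- Checkpoint selection tie-break: later iteration.
- Empty-class metric conventions: 0/0 → 1.0.
- Seeding: a single master seed fans out via `SeedSequence.spawn` to
  scene generation, data sampling, cropping and weight init.

## Known limitations

- CPU-only NumPy compute: the full W48/512-crop configuration is
  impractical to train here; it is expressed and validated structurally
  (shapes, parameter census, exchange-unit counts) and exercised at
  reduced width.
- Binary task only; the head is K-generic but nothing beyond K = 2 is
  tested.
- No CRF/TTA post-processing, no mixed precision, no multi-GPU, no
  early stopping.
- Whole-image validation scoring during training can be slow for very
  large validation images; validation sets at full scan size should be
  small or pre-cropped.
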