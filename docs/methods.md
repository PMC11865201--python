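# Methods

## Model

The classifier maps an RGB leaf crop (default 448×448×3) to class logits
through a stem convolution, thirteen inverted-residual blocks and a
convolutional head. The design goal is parameter economy at useful
accuracy; every architectural choice below serves that trade-off.

**Block variants.** `DW_IR` applies a depthwise convolution (+BN+relu6),
an efficient-channel-attention (ECA) gate, and a pointwise projection
(+BN, no activation); it performs no channel expansion. `DSC_IR` is the
classic inverted residual: pointwise expansion (+BN+relu6), depthwise
filter (+BN+relu6), pointwise projection (+BN, no activation).
`DSC_ECA_IR` adds an ECA gate after the projection, acting on the output
channels, before the residual add. An identity skip wraps a block iff its
stride is 1 and input and output channel counts match. Activation is
relu6 = min(max(0, x), 6) throughout; the projection stage is
deliberately linear (BN only), which preserves information through the
low-dimensional bottleneck.

**ECA gate.** Global average pooling reduces each channel to a scalar;
a single shared k-tap 1-D convolution (zero "same" padding, no bias) mixes
each scalar with its neighbours; a sigmoid yields per-channel weights in
(0, 1) that rescale the feature map. k is the nearest odd integer to
`log2(C)/γ + b/γ` with γ = 2, b = 1, resolved upward from an even value
(t = ⌊log2(C)/γ + b/γ⌋, k = t or t+1); at the gated widths of this
network (16, 24, 40, 48) k is always 3, so each of the eleven gates costs
exactly 3 parameters and attention costs 33 parameters in total.

**ECA placement.** Inside `DSC_ECA_IR` the gate sits on the output
channels (16–48) rather than the expansion channels (88–288). At output
widths the eleven gates cost 3 parameters each — the +33 total that
separates the full network (418,181) from the attention-free ablation
(418,148); at expansion widths the rule would charge 47 parameters across
the same rows and the totals would not reconcile. In `DW_IR` the gate
follows the depthwise stage (the block's only 16-channel site either way).

**Parameter conventions.** Backbone convolutions are bias-free and
followed by affine batch normalisation (2 learnable scalars per channel).
The head's 288→512 and 512→num_classes 1×1 convolutions carry biases and
no BN. Under these conventions the closed-form ledger

```
464 + 467 + 3864 + 5416 + 5419 + 9011 + 2×26243 + 14139 + 18099
    + 4×36099 + 14400 + 147968 + 2052 = 418181
```

is reproduced exactly by tensor-by-tensor enumeration of the built
network, and is asserted for every variant in the tests.

**Padding.** Convolutions use "same" padding with ceil division under
stride, so a stride-2 stage maps H → ⌈H/2⌉ and the tabulated output sizes
(224 → 112 → 56 → 28 → 14 → 7 at the 448 input) follow.

## Implementation

The network — forward pass, backpropagation, batch normalisation, dropout,
ECA, softmax cross-entropy and Adam — is implemented directly on numpy
(float32, NCHW; convolutions via strided sliding-window views and einsum).
Gradients of every layer were verified against central finite differences.
The public surface is a scikit-learn estimator
(`LeafDiseaseClassifier.fit/predict/predict_proba`), so the model composes
with sklearn model selection; module-level functions and the CLI are thin
wrappers over it.

## Training choices

- **Loss/optimiser:** cross-entropy with Adam (lr 1e-3, β 0.9/0.999),
  batch size 32, no weight decay, no class weighting. All configurable.
- **Initialisation:** Kaiming fan-out normal for convolutions, BN scale 1 /
  shift 0 — except the final 512→num_classes convolution, which is
  zero-initialised. Fan-out at that layer (fan = num_classes) would give
  logits of order unity times √512 and a poorly conditioned start; the
  zero start makes the first prediction exactly uniform and lets short
  runs descend immediately. Backbone init scale is largely neutralised by
  BN.
- **Batch-norm statistics:** training uses batch statistics with an EMA
  (momentum 0.1) for inference. After the epoch loop, the EMA is replaced
  by cumulative batch statistics computed in one extra pass under the
  final weights. Short runs otherwise leave the EMA dominated by
  early-training activations, and inference-time normalisation then
  mismatches the weights (observed as near-constant eval logits after a
  few epochs of training).
- **Dropout:** rate 0.2 between the last two head convolutions
  (conventional for this family; parameter-free, so ablation totals are
  unchanged). The `no_dropout` variant omits the stage; its eval-mode
  forward is bit-identical to the full variant's.
- **Determinism:** one seed drives initialisation, batching, dropout and
  splits; eval-mode inference is bit-identical across runs on a platform.

## Augmentation protocol

Fourteen environments: `original` plus flips, brightness/chroma/contrast/
sharpness ×1.5 ("increase") and ×0.5 ("reduction"), Laplacian sharpening
(image + 3×3 Laplacian response), gamma 1.5, and CLAHE. "Chroma" is
colour-saturation enhancement. Enhancement factors use the standard
image-enhancement convention (1.0 = identity). CLAHE runs with clip limit
0.02 (normalised histogram fraction, ≈ the classic count-based clip of 2)
on an 8×8 tile grid; a zero-range image is returned unchanged (degenerate
histogram). All transforms are deterministic, preserve image size and
channel count, and flips additionally preserve the pixel multiset.

Expansion is exactly 14-fold and lazy: records are (source, environment)
metadata, pixels are produced on demand, so counting at the published
class sizes costs nothing. Splitting is per class with ceil rounding on
the training side (968 → 775/193, 2335 → 1868/467, 1441 → 1153/288,
1257 → 1006/251) under a seeded permutation.

Evaluation scores one accuracy (micro: correct/total) per environment on
that environment's expansion of the held-out images, using one model
across all environments, and reports the arithmetic mean of the rows.

## Synthetic data

The generator emulates a single leaf (rotated, wobbled ellipse) on a
soil-toned background. Healthy leaves are veined green; powdery mildew
adds a bright whitish high-frequency speckle (≈10% coverage); late blight
adds large dark blotches (≈40% of the leaf, correlation length ≈10 px at
the 64-px scale); leaf mould adds mid-tone ochre patches (≈40%,
≈6 px). Texture length-scales are stated at 64 px and scale linearly with
image size. Every pixel is determined by (seed, class, index).

What it does and does not show: the classes are genuinely separable from
pixels (a logistic probe on channel means/standard deviations reaches
≈0.87 cross-validated accuracy, chance 0.25), so end-to-end tests
demonstrate that the network, training loop and evaluation harness work
and can learn. The textures are not photorealistic — no camera noise,
occlusion, specular highlights, or background clutter — so accuracies on
synthetic data say nothing quantitative about field imagery, and the
package makes no such claim.

## Problem sizes used in tests

The default test and acceptance runs use 64×64 images, 50 per class, an
8:2 split, 14-fold expansion of the training split (2,240 records) and 3
training epochs — sizes chosen so the full pipeline exercises every code
path in minutes on one CPU while clearing the 0.60 held-out accuracy bar
by a wide margin (typically ≥ 0.9). The 448-px input contract is what the
shape tests assert; smaller inputs are an explicit configuration
(`image_size`), which rescales the stem input while keeping the
channel/stride table fixed.

## Known limitations

- No GPU path; wall-clock training at 448 px full scale is impractical in
  this implementation (it exists for correctness, small-scale training and
  accounting, not throughput).
- Reported field accuracies of the original study are out of scope: they
  require the unreleased photographed dataset and GPU-scale training.
- The leaf-crop interface consumes external bounding boxes; no detector is
  included.
- BN recalibration adds one forward pass over the training set per fit.
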