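# Methods

## The multi-scale block

A standard U-Net stage applies two stacked 3×3 convolutions, so every stage
sees one fixed receptive field. The multi-scale block widens that choice:
several *branches*, each a sequence of two same-padded convolutions with its
own kernel size k ∈ {1, 2, 3, 5, 7, 9}, process the same input in parallel.
For the canonical two-branch block "(37)":

    x₁ = W₃₂(W₃₁ x + b₃₁) + b₃₂          (3×3 branch)
    x₂ = W₇₂(W₇₁ x + b₇₁) + b₇₂          (7×7 branch)
    X  = Cat[x₁, x₂]
    F  = W_f X + b_f                      (1×1 reduction)

Branches never share weights. With branch width `out_channels` the
concatenation has `k·out_channels` channels and the 1×1 convolution reduces
it back to `out_channels`, so a block is a drop-in replacement for a plain
double-conv stage.

The canonical family pairs the 3×3 kernel with every non-empty subset of the
other five sizes: 31 configurations, named by their sorted kernel digits
("13" … "123579"). Variants:

* **sum fusion** ("37+sum"): branch outputs are added elementwise instead of
  concatenated; the 1×1 reduction is kept so the two fusion modes differ only
  in the fusion operator.
* **serial** ("37+concatenated", "73+concatenated"): the two kernel stages
  are chained (two convs of the first kernel, then two of the second), with
  no parallel split and no 1×1 fusion. Order matters only through the learned
  parameterization; the shape contract is identical.
* **dilated** ("37+dilated"): the 7×7 branch is replaced by a 3×3 kernel at
  dilation 3. The effective receptive width, dilation·(k−1)+1 = 7, is
  preserved while the weight count drops by a factor ≈ 49/9.
* **residual (1)** ("res1:…"): the raw input joins the fused concatenation,
  `X_R = Cat[x_r, x_r1, x_r2]`, so the 1×1 reduction sees
  `in_channels + k·out_channels` inputs.
* **residual (0)** ("res0:…"): an additive skip around the whole block. The
  fused output is summed with the input, routed through a 1×1 projection
  when the widths differ and the identity otherwise. Since the concatenating
  form is already variant (1), the additive skip — the canonical residual
  wiring — is the natural second design. No activation follows the addition, so
  a zero-initialized block path is an exact (bitwise) identity — a property
  the tests rely on.

### Per-convolution micro-architecture

The block equations above fix the convolutions but not the normalization or
activation around them. Default:
Conv → BatchNorm → ReLU for *every* convolution, including the 1×1 fusion
conv (`norm=False` recovers bare conv+ReLU in original-U-Net style, and is
what the closed-form parameter examples in the tests use). Convolution
weights are He-normal (fan-in); biases start at zero; all initialization is
drawn from one seedable generator so a (spec, seed) pair rebuilds bitwise
identical networks.

Same-padding for the even 2×2 kernel is asymmetric (extra pixel on top/left)
so that every kernel in the family preserves spatial dimensions — the whole
assembly logic depends on that contract.

## Architectures

`NetworkSpec` describes an assembly: depth (`levels`, default 5), level-1
width (`base_width`, default 64, doubling per level), a block name or
"plain", block placement (both paths / encoder only / decoder only),
upsampling (transposed 2×2 conv, default, or fixed bilinear), and skip mode
(plain concatenation, additive attention gates, or the nested dense-skip
grid). Skips concatenate as `[skip, upsampled]`. The head is a 1×1
convolution plus sigmoid: all tasks here are binary, per-pixel foreground
probability.

The attention gate projects skip and gate to an intermediate width with 1×1
convolutions (the skip projection is average-pooled to the gate's
resolution), sums, applies ReLU, reduces to one channel, applies a sigmoid,
and nearest-upsamples the coefficient map back to the skip resolution.

The nested variant builds the triangular grid X^{i,j}: node (i, j) consumes
the upsampled X^{i+1,j−1} concatenated with X^{i,0..j−1}; L levels give
L(L+1)/2 conv nodes. Deep supervision is off.

**Wide U-Net.** Comparing a multi-scale network against a plain U-Net is
confounded by parameter count, so `build_wide_unet` solves for the width
multiplier (bisection over [1, 8] on a closed-form parameter count) that
brings a plain U-Net within a tolerance (default 10 %) of the reference's
parameter total. The closed-form count is verified in tests against a
brute-force walk over every built network's parameter containers.

## Numerical core

No deep-learning framework is used: `msunet.nn` is a compact reverse-mode
autodiff engine over numpy arrays. Convolutions are stride-1 im2col + BLAS
matrix products with arbitrary asymmetric padding and dilation; the input
gradient is the correlation of the output gradient with the spatially
flipped, channel-transposed kernel under complementary padding. Transposed
convolution is zero-insertion followed by a convolution, so its gradient
needs no special case. Batch normalization, pooling, and the fused BCE /
soft-Dice losses implement their standard analytic gradients. Every
operation is checked against central finite differences, and the convolution
additionally against `scipy.signal.correlate2d`. Activations and parameters
are float32; gradient-check tests run in float64.

## Training and evaluation protocol

Optimization: SGD with learning rate 1e-2 and momentum 0.9, no weight decay,
no schedule. The loss is binary cross-entropy by default, with soft Dice and
BCE+Dice selectable. Epochs and batch size are config, not constants; batch
size defaults to 4.

Splits: images are randomly divided into six near-equal subsets; subset 6
(configurable) is the held-out test set; the remaining pool is partitioned
into five validation chunks, giving five folds at a 4:1 train:validation
ratio. Every fold trains from the same initial weights; the per-fold model
is the checkpoint with the best validation IoU; fold models are scored on
the test subset and reported as mean ± sample SD (n−1), with pooled-variance
two-sample t-tests for between-architecture comparisons.

Metrics are micro-averaged: confusion counts are pooled over all pixels of
the evaluation set at a 0.5 binarization threshold (both exposed as
options). Degenerate denominators resolve to 1 when prediction and truth are
both empty, 0 otherwise. AUC is computed on raw probabilities
(trapezoidal/midrank, via scikit-learn) and equals the Mann–Whitney pairwise
fraction — a property the tests verify against a brute-force pairwise count.

## Synthetic data

The generator emulates the *shape* of common binary segmentation modalities,
not their physics:

| style | emulates | image | mask foreground |
|---|---|---|---|
| blobs | ultrasound/dermoscopy lesions | dark ellipses on bright speckled field | lesion |
| membranes | electron microscopy | bright Voronoi-cell interiors, dark walls | cell interiors (white) |
| bilobe | chest-radiograph lung fields | two dark smooth lobes | lobes |
| nuclei | histology nuclei (3-channel) | many small dark blobs | nuclei |

Images are smoothed, optionally speckled (multiplicative Gaussian) and
additively noised, clipped to [0, 1]; 8-bit on disk (`images/` + `masks/`
PNG or TIFF trees, masks {0, 255}), float32 in memory, row-major,
origin top-left. Default size 64 px (any multiple of 16 works). Everything
is reproducible from (style, n, seed).

What passing on these fixtures does **not** show: robustness to anatomical
variability, intensity non-uniformity, annotation noise, class imbalance at
realistic scales, or any transfer to real scanners. The fixtures verify the
machinery — shapes, gradients, protocol arithmetic, learnability — not
clinical performance.

## Problem sizes

The end-to-end check trains MSU-Net(37) at base width 16 and 4 levels on one
cross-validation fold of 120 blob images (64 px, seed-fixed) for 15 epochs —
small enough for a laptop CPU, large enough that the trained network's
held-out IoU (≈ 0.95) cleanly separates from the untrained one (≈ 0.15).
Ablations default to toy budgets (n=30, shallow widths); the full 31-block
enumeration is available through `msunet ablate --names all31`.

## Known limitations

* Stride-1 convolutions only (downsampling is pooling; upsampling is
  transposed conv / bilinear) — sufficient for this family, not general.
* Single-channel or RGB 2-D inputs; binary output head only.
* The bilinear upsampler uses zero padding at borders, so the outermost ring
  is slightly attenuated relative to interpolators with edge replication.
* CPU-only and single-process; the im2col buffers make memory scale with
  batch size, so large images favor small batches.
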