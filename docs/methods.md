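# Methods

## The detector

`encanet` implements a single-level anchor-based detector for blood-smear
microscopy (three categories: platelets, RBC, WBC), organised as
**Backbone → Encoder → Decoder**:

* **Backbone** — an EfficientNet feature extractor (compound-scaled variants
  B0–B3, classifier head removed). A `N×3×416×416` input yields a single
  stride-32 map (`13×13`) of width 1280/1280/1408/1536. The stack follows
  the standard scaling rules (channel widths rounded to multiples of 8,
  ceil-scaled stage depths, squeeze-excitation width = block input // 4,
  final 1×1 expansion to 4× the last stage width); this reconstruction is
  pinned by exact parameter-count agreement with the reference models
  (B0 features: 4,007,548 trainable parameters).
* **Projection** — a 1×1 convolution (with bias) to a fixed 512 channels,
  followed by batch norm. The bias is deliberate: it is the convention under
  which every printed two-decimal parameter total of the detector family
  reproduces exactly (see "Parameter audits").
* **Encoder** — a pluggable feature-recalibration stage at 512 channels:
  `none`, SE, ECA, CAM (the channel half of CBAM), ECAM, SAM (spatial
  attention), CBAM, ECBAM, or (for comparison audits only) the dilated
  residual encoder that this design removes.
* **Decoder** — two parallel heads built from depthwise-separable modules
  with residual connections (2 for classification, 4 for regression;
  268,800 parameters each at 512 channels), then 3×3 predictors for `K·A`
  class logits, `4A` box deltas and `A` objectness logits (`K`=3 classes,
  `A`=5 anchors per cell).

## Attention mechanisms

All gates are multiplicative and strictly inside (0,1) (sigmoid outputs).
With `z_c` the spatial mean of channel `c`, `m_c` the spatial max, and a
shared bottleneck MLP `W₂ δ(W₁ · + b₁) + b₂` (reduction ratio `r`, ReLU δ):

* SE: `P = σ(MLP(z))`
* CAM: `P = σ(MLP(z) + MLP(m))` — one shared MLP, two evaluations
* **ECAM**: `z′_c = σ(m_c) · z_c`, then `P = σ(MLP(z′))` — the max branch
  acts only through a sigmoid gate, so one MLP evaluation replaces CAM's
  two. For fixed `z_c > 0`, `z′_c` is strictly increasing in `m_c`; with the
  gate forced to 1 the mechanism is bit-for-bit the SE path.
* ECA: 1-D convolution (no bias) over `z` with adaptive odd kernel
  `k = odd(⌊(log₂C + 1)/2⌋)` → k=5 at C=512.
* SAM: channel-wise mean and max maps stacked into a 2-channel image,
  convolved `k×k` (bias, zero padding `(k−1)/2`, default k=7), sigmoided.
* CBAM / **ECBAM**: channel stage (CAM / ECAM) then SAM, sequentially.

Choices the sources leave open, fixed here: the MLP carries biases (`b₁`,
`b₂`) — the only convention reproducing all printed totals; the sigmoid gate
is applied to the raw `m_c` without normalization; batch handling is
per-sample (descriptors are `(N, C)`), and the sigmoid is evaluated in a
numerically stable form (no overflow at |x| > 30).

## Parameter audits

`audit_params` instantiates a configuration and enumerates every trainable
array (batch-norm affine pairs counted; running statistics not). This
reproduces, at two-decimal millions rounding: 6.46 (B0 baseline), 8.97 /
10.22 / 13.28 (B1–B3 baselines), 6.49 (+ECAM or +SE or +CAM), 6.5 (+ECBAM
or +CBAM), 6.46 (+ECA, +SAM), the reduction-ratio sweep 6.72/6.59/6.53/
6.5/6.48 (r = 2…32), the kernel sweep 6.49/6.49/6.5/6.5/6.5 (k = 3…11),
and the 3,484,160-parameter (3.48 M) dilated-encoder delta. The audits are
additive: every attention variant's total equals the baseline plus the
closed-form `attention_param_count`.

One printed figure is *not* reproduced: the 9.94 M total for the baseline
*with* dilated encoder is 0.01 M off the sum of the separately printed
6.46 M and 3.48 M under any exact count, so only the delta is audited.

## Training machinery

The training recipe the detector family inherits: SGD (momentum 0.9, weight
decay 1e-4), batch size 4, base learning rate 0.12 held constant after a
linear warmup over the first 1500 iterations starting at 1/1000 of the base
(the sources state no decay schedule; constant-after-warmup is declared
here). Anchors are square ({32,64,128,256,512} px at image size 416, scaled
proportionally at other sizes), targets assigned by uniform matching: each
ground-truth box claims its k=4 nearest anchors by center distance;
positives with IoU < 0.15 to their box are demoted to ignored, and
unmatched anchors with IoU > 0.7 to any box are ignored. Losses: focal
(α=0.25, γ=2) on the combined `sigmoid(class)·sigmoid(objectness)` score,
GIoU on decoded positive boxes, and an L1 term on the box deltas, all
normalized by the number of positives. The delta L1 term and global
gradient-norm clipping (default 10) are stabilizers this implementation
adds: with batch 4 and random initialization, GIoU alone lets mis-centered
early predictions inflate into a vanishing-gradient regime. The predictor
heads are initialized with small weights and a background-prior bias
(π = 0.01), standard for focal-loss detectors.

Because per-batch normalization statistics are noisy at batch 4 on a coarse
grid, `recalibrate_batch_norm` replaces running statistics by exact
activation moments averaged over the training set after optimization;
evaluation always follows recalibration.

Inference: score floor 0.05, per-class greedy NMS at IoU 0.6, at most 100
detections per image. Evaluation implements the MS-COCO protocol (IoU
0.50:0.05:0.95, 101-point interpolated precision, area splits at 32² and
96², AP averaged over categories with ground truth), reported on the 0–100
scale; it is cross-checked in the tests against an independent brute-force
PR accumulation.

## Synthetic smear scenes

The generator emulates the class structure of a stained smear field at
416×416: 10–40 RBC-like ellipses (semi-axis 14–26 px, pale red), 1–3
WBC-like cells (28–44 px, violet, rendered as nucleus + cytoplasm for
texture), 2–8 platelet-like specks (4–9 px), bounded eccentricity (axis
ratio ≤ 1.4), per-object color jitter, rejection sampling against a
same-class box-IoU cap of 0.3 (an object is dropped with a logged warning
after 100 failed placements), soft ellipse edges and additive Gaussian
noise (σ = 5). Scenes are deterministic in (config, seed); datasets derive
per-scene seeds as `seed + index` so they extend without reshuffling.
`SceneConfig.scaled(s)` shrinks radii by `s/416` with counts unchanged, for
scaled-down studies. The generator does **not** model stain variation, cell
clumping, focus blur or real smear statistics — passing pipeline tests
shows the machinery optimizes and evaluates correctly, not that the
detector would reach any particular accuracy on real microscopy data.

## Problem sizes used by the test suite

Parameter audits and operator-level checks run at full scale (they are
seconds of work). The stochastic pipeline checks run at reduced input sizes
with geometrically scaled scenes (radii scale with the side ratio, object
counts with the area ratio, so density per grid cell matches the reference
scene) and proportionally scaled anchors, chosen so the whole suite stays
desk-scale on one CPU core: the detection smoke test trains at input 96
(40 scenes, 300 iterations, 5 seeds) and the loss-decrease property at
input 64 (one fixed 8-image batch, 200 iterations, 10 seeds).

A caveat the tests make explicit: with a randomly initialized backbone,
~1200 image-views train the classification pathway and reduce the loss
reliably, but are far too few to learn precise box regression — features
at stride 32 carry no localization signal until the backbone itself has
trained, so held-out AP at such smoke scales remains near zero. Detection
accuracy claims require pretrained weights and orders of magnitude more
optimization; the smoke tests verify that the machinery optimizes and
evaluates correctly, and the accuracy-level smoke test documents this gap
rather than papering over it.

## Numerical choices

float32 throughout the network (the audit facility is integer arithmetic);
He initialization for convolutions; BN ε = 1e-5, momentum 0.1; box-delta
log-sizes bounded to ±8 in the loss with a pass-through gradient (a hard
clip would zero the restoring gradient once exceeded) and ±10 at decode
time; sigmoid via `expit`; loss logits clamped to ±15 so float32 sigmoids
stay strictly inside (0,1); NMS ties broken by stable descending-score
order; degenerate min-max normalization in attention maps maps a constant
feature map to all zeros.

## Known limitations

* The network layer is a from-scratch numpy/numba implementation: correct
  (gradient-checked against numerical differentiation) but far slower than
  GPU frameworks; training beyond smoke scale is impractical.
* Backbone weights are randomly initialized; the accuracy figures reported
  for this detector family on real data presume a pretrained backbone,
  hours of training and the real datasets, and are out of scope here.
* GFLOPS figures are not audited: the printed values follow a counting
  convention that no standard FLOP count reproduces at stride 32.
* COCO "crowd" regions are not modeled (the synthetic data has none).
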