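# Methods

This note records the modelling conventions, numerical choices and open
design decisions behind the package, and what the bundled tests do and do
not demonstrate.

## Selective scan

The S6 recurrence is implemented with zero-order-hold discretisation of the
learned decay matrix and Euler discretisation of the input matrix:

```
h_t = exp(delta_t * A) ⊙ h_{t-1} + (delta_t * B_t) * u_t,   h_0 = 0
y_t = C_t · h_t + D ⊙ u_t
```

with `A = -exp(A_logs)` strictly negative, `delta_t = softplus(dt_proj(dt_t))`
strictly positive, and `B_t`, `C_t`, `dt_t` produced per token by the
low-rank `x_proj`.  The scan state is accumulated in float32 at minimum
(float64 inputs stay float64).  The implementation is a sequential loop over
tokens, vectorised over batch, channels and state; there is no fused or
parallel-prefix kernel, and no bidirectional variant.  Its correctness is
checked against an independent per-token, per-batch recurrence oracle and
against central finite differences for every gradient.

Initialisation follows standard stable-SSM practice: `A_logs` is the log of
a repeated `[1..d_state]` row, `D = 1`, and the `dt_proj` bias is the
inverse softplus of a log-uniform draw from `[1e-3, 1e-1]`, so initial step
sizes start small and positive.

`dt_rank="auto"` resolves to `ceil(d_model/16)` floored at 1.  The floor
matters: the parallel layer's branch widths (6, 8, 12, 16 channels) would
otherwise round the rank to zero and leave the step-size projection empty.

## SS2D scan geometry

The four directions are: row-major from the top-left; its reverse;
column-major starting at the top-right column, each column traversed top to
bottom; and its reverse.  The prose convention only names the corner pairs,
so the within-column order is a package choice, fixed and tested
(expand-then-merge sums four reconstructions, i.e. equals 4x the input
exhaustively for all H, W <= 6).  Parameter counts are independent of this
choice.  Each direction uses its own slice of `x_proj`, `dt_proj`,
`A_logs` (shape `(4*d_inner, d_state)`) and the skip gain `Ds`.

## Parameter accounting conventions

Two conventions for the internal convolution term are first-class:

- **paper_formula** — dense convolution: `d_conv * d_inner^2 + d_inner`
  (1-D) and `d_conv^2 * d_inner^2 + d_inner` (2-D).  This is the convention
  of the closed-form analysis and reproduces the 23,435,264 / 1,484,288 and
  45,504,512 / 2,921,984 block totals exactly.  The published 2-D term is
  printed as `3^2 * d_inner^2`; only that reading reproduces the totals.
- **reference_depthwise** — grouped convolution with bias:
  `(d_conv + 1) * d_inner` (1-D), `(d_conv^2 + 1) * d_inner` (2-D).  This is
  what constructed and trained blocks actually contain, and what the
  0.049M model total requires.

The dense-conv closed form and the depthwise construction are mutually
inconsistent at the model level (a dense internal conv would blow the
0.049M budget); both are exposed and the audit table reports which one is
in use, so the discrepancy is visible rather than hidden.  The two-way
parallel ratio at C = 1024 is 0.502; the four-way ratio computed from the
same formulas is 0.2533 (4 x 1,484,288 / 23,435,264), and the model-level
reduction it implies is 74.67 %.

## PVM layer and weight tying

`PVMLayer` defaults to **shared branches**: one Mamba block, one scalar
residual factor `theta` (initialised to 1.0, learnable) and one LayerNorm
whose affine parameters are applied both before the split and after the
concatenation.  This tying is required to reach the published model budgets
(49,454 parameters with k=4; 69,586 with k=2; 136,266 with k=1; 32,843 with
bridges off); fully independent branches are available via
`shared_branches=False` and roughly quadruple the PVM-stage cost.  Shared
weights keep the functional branch structure — groups are processed
independently (verified by locality and group-permutation tests) — they
just see the same parameters.  The projection is a pointwise linear map
with bias and performs the stage's channel change.

## Model assembly

Six stages, channels `[8, 16, 24, 32, 48, 64]`.  Encoder stages 1-5:
block -> GroupNorm(4 groups) -> 2x2 max pool -> ReLU; their five outputs are
the skip tensors.  Stage 6 is a PVM layer at the 1/32 resolution without a
further pooling.  The bridges gate the five skips: SAB (channelwise
mean+max -> one shared 7x7 convolution -> sigmoid -> `gate*x + x`) then CAB
(global average pooling, concatenated across stages to a 128-vector, one
linear map per stage -> sigmoid channel gate with residual).  The decoder
applies its block at the coarse resolution and then upsamples (first
decoder stage: no upsampling), using parameter-free bilinear interpolation
(align_corners), with skip fusion by elementwise addition; a 1x1
convolution head and a final 2x upsampling produce the sigmoid probability
map.  ReLU is used throughout (the choice of pointwise nonlinearity does
not affect any audited count).  Input sides must be square multiples of 32
(five poolings); 64, 128 and 256 are the tested sizes.

## MAC profiling

`flops_count` reports giga multiply-accumulates of one forward pass.  The
default **fused** convention counts convolutions (2-D everywhere, plus the
short causal 1-D convolution in each Mamba) and standalone linear layers
(PVM projections, channel-attention maps), while treating the selective
scan path — its in/x/dt/out projections and the recurrence — as one opaque
primitive, the way module-hook profilers see models whose scan executes as
a fused kernel.  Under this convention the default model measures
0.060 GFLOPs at 3x256x256 and 0.058 with the bridges removed.  The **full**
convention additionally counts the SSM projections and scan
multiply-accumulates (about 0.073 GFLOPs for the default model).
Normalisations, activations, pooling and interpolation are never counted.

## Metrics and loss

Metrics are micro-averaged: confusion counts are pooled over all pixels of
the evaluation set, then DSC, SE, SP, ACC, IoU and precision are formed.
Predictions are thresholded at 0.5.  A metric whose denominator is empty
(e.g. specificity on an all-foreground image set) reports 1.0 — the ideal
is vacuously met — which avoids NaNs when aggregating; the event is logged
at debug level.  The training loss is `w_bce * BCE + w_dice * (1 - Dice)`
with 1:1 weights, probabilities clamped at 1e-7 and Dice smoothing 1.0.

## Synthetic data

The generator emulates the *format* of dermoscopy lesion datasets, not
their difficulty: a skin-toned background with a gentle linear gradient and
smoothed multiplicative Gaussian texture (sd 0.04), one or two darker
elliptical lesions (semi-axes 10-35 % of the image side, random
orientation) with low-order harmonic boundary wobble and a radial
darkening profile (centre factor 0.45-0.70); the mask is the crisp union of
the lesion regions.  If lesions cover >= 55 % of the image the axes are
shrunk by 0.8 and redrawn, bounding the foreground fraction below 0.6
while keeping it positive.  Identical specs give bitwise-identical data.

Real dermoscopy images have hair, rulers, specular highlights,
low-contrast and multi-textured lesions; nothing here models those, so a
high DSC on synthetic data demonstrates that the architecture, gradients
and training loop work — not clinical performance.  Published accuracies on
real benchmark datasets are out of scope for this package's tests.

Augmentation: horizontal/vertical flips (p = 0.5 each) and rotation by a
uniform angle in +-30 degrees with edge reflection, image bilinear, mask
nearest-neighbour; one seed per (epoch, sample).

## Training and desk-scale study size

Defaults mirror the standard recipe: BCE+Dice, AdamW (weight decay 0.01),
batch 8, cosine annealing from 1e-3 to 1e-5 over the run (single period),
250 epochs.  The learnability check used in the tests runs the scaled-down
configuration — 100 synthetic 128^2 images split 70/10/20, 30 epochs —
which one CPU core completes in a couple of minutes and which reaches a
validation DSC around 0.94.  The single-sample memorisation check disables
augmentation and weight decay (both fight memorisation) and runs 400
steps.  Training aborts with a diagnostic on a non-finite loss.  Everything
(init, shuffling, augmentation) derives from one integer seed;
single-threaded runs are exactly reproducible.

## Known limitations

- No GPU path and no fused scan kernel: wall-clock performance is adequate
  for desk-scale experiments only.
- The component ablations that replace PVM stages by plain convolutions are
  implemented as switches but no external parameter totals are claimed for
  them.
- The high-order 2-D scan variant (H-SS2D) is not implemented; the
  accounting covers Mamba and SS2D blocks only.
- Checkpoints store raw arrays plus the config as JSON inside an `.npz`;
  they are not interchangeable with other frameworks.
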