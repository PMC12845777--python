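# Methods

## The problem

Weed detection in cotton fields is a single-stage object detection task
under tight compute budgets: models are deployed on field equipment, so
every added attention block must pay for itself.  Channel attentions
(SE, ECA) are cheap but discard spatial structure; full spatial
attentions (CBAM's 7x7 spatial gate, coordinate attention) recover it at
a parameter and latency cost.  Group-enhanced fusion attention (GEFA)
sits between the two: grouped convolution enhances features cheaply, and
a local-region gate restores coarse spatial selectivity at almost no
parameter cost.

## The GEFA operator

For a feature map `x` with `C` channels:

1. **Group enhancement.**  Channels are partitioned into `G` equal
   groups.  A grouped `k x k` convolution expands each group by a width
   factor `w` (hidden width `round_G(w*C)`, a multiple of `G`), followed
   by batch normalization and SiLU; a grouped `1x1` convolution projects
   back to `C` channels with a second batch normalization.  Group
   outputs are concatenated along the channel axis, giving enhanced
   features `U`.  Grouping divides both weight count and compute by `G`.
2. **Local branch.**  `U` is average-pooled onto a `p x p` grid of
   regions (local average pooling, LAP).  A single learned 1-D filter of
   length `k(C)` is convolved along the channel axis of the region
   descriptors (zero padding, no bias), and the result is expanded back
   to `H x W` by nearest-neighbour de-pooling.
3. **Global branch.**  The same 1-D filter is applied to the globally
   averaged descriptor.
4. **Fusion and residual.**  The gate is
   `A = sigmoid((local + global) / 2)`, elementwise in (0,1), and the
   output is `y = x + A * U`.

The 1-D kernel size follows the adaptive rule

    k(C) = odd( log2(C)/gamma + b/gamma ),   gamma = b = 2

where `odd(v)` rounds half up to the nearest integer, adds one if the
result is even, and clamps to a minimum of 3.  The formula can produce
non-integers and the published statement only requires oddness;
round-half-up-then-increment is our deterministic reading, and both
`gamma` and `b` default to 2 with either overridable in the config.

Design choices that were genuinely open, and how we fixed them:

- **Branch fusion** is the parameter-free arithmetic mean before the
  sigmoid (symmetric in the two branches).  An alternative (product of
  two sigmoids) changes nothing structurally; the mean keeps one gate.
- **Mixer sharing**: the 1-D filter is shared between the local and
  global branches by default (`share_mixer`), with a flag to duplicate
  it.  Sharing is consistent with treating the global descriptor as the
  `p = 1` special case of the local one.
- **Degenerate shapes**: inputs with `H < p` or `W < p` raise instead of
  silently shrinking the grid, so profiled complexity always matches
  executed complexity.
- **Hidden width rounding**: `w*C` is rounded half-up to a multiple of
  `G` so the operator is defined for any `C` divisible by `G`; at the
  channel widths where GEFA is actually inserted (64..512 at width
  multiple 0.5) the rounding is exact.

## The detector

The host network is the v6-generation small single-stage layout: a 6x6
stride-2 stem convolution, four conv + C3 backbone stages at base widths
{128, 256, 512, 1024} scaled by `width_multiple = 0.50` and rounded to
the nearest multiple of 8, SPPF (k=5) at the backbone end, a PANet neck
(two top-down, two bottom-up paths, C3 blocks without shortcuts), and
three 1x1 biased head convolutions emitting `3*(nc+5)` channels at
strides 8/16/32.  C3 repeat counts scale as `max(1, round(n *
depth_multiple))` with `depth_multiple = 0.33`.  This layout is the one
whose exact parameter counts (7,235,389 at 80 classes; 7,073,569 at 20)
truncate to the published baseline cells (7.23 M / 7.07 M).

`AttentionC3` is a C3 block whose output passes through a pluggable
attention operator; with variant `none` it is parameter-for-parameter a
plain C3.  Attention slots are the four backbone C3s (`P2..P5`) and the
four neck C3s (`N1..N4`).

Comparison attentions (SE with reduction 4, ECA, coordinate attention
with reduction 16, CBAM with reduction 16, MLCA on a 5x5 grid) follow
their published definitions behind the same plug-in interface, so any of
them can replace the attention slot.  Two deliberate readings: CA uses
SiLU in place of hard-swish for consistency with the host network, and
MLCA fuses its local and global descriptors with the same
mean-then-sigmoid rule as GEFA.

## Complexity accounting

Parameter counts are exact integer sums over learned weights
(convolution kernels, biases, normalization scale/shift); running
statistics are not learned and are excluded.  The mega-scale figure
truncates to two decimals — the convention evident in the published
tables (7.2353.. prints as 7.23).

FLOPs are counted analytically from the layer graph under one frozen
convention: 2 per convolution multiply-accumulate, 1 per bias add, 2 per
normalized element (scale, shift), 5 per activation (one sigmoid/SiLU
evaluation: exponential, add, divide, multiply), 1 per remaining
elementwise op (residual adds, gating products, pooling compares).  The
elementwise prices were calibrated once so that the attention-free
baselines at 640x640 reproduce the published 16.6 GFLOPS (80 classes)
and 16.1 GFLOPS (20 classes) simultaneously, then frozen for every
variant.  Published profilers disagree on exactly these terms, so the
baseline cells are the only anchor available; the two cells constrain
the convention jointly and one price vector satisfies both.

The GFLOPS cells published for the *comparison* attentions (about +1.3 G
for SE or ECA) are not reproducible from the published module
definitions at C3-output insertions under any elementwise pricing —
a pooled-descriptor attention touches too few elements.  Those cells are
therefore reported by our profiler as what the definitions imply, not
forced to match.

## GEFA calibration

The published parameter cells are the only machine-checkable ground
truth for GEFA's size, so its free hyperparameters (G, group kernel,
width factor, placement) are fixed by search rather than a priori.
Because attention never touches the detection head, one weight delta
must explain both class counts: the admissible interval is

    [7.39, 7.40) M - 7,073,569   intersect   [7.55, 7.56) M - 7,235,389
    = [316,431 , 324,611) added weights.

`calibrate_gefa` enumerates G in {4, 8, 16, 32}, group kernel in
{1, 3}, width factors on a grid of eighths (1/8 .. 2) plus small
integers (3..8), and placement in {backbone, backbone + neck}, computes
each delta in closed form, and returns the configuration that lands in
the interval — verifying it against a fully built model.  The search
finds `G = 8`, group kernel 1, width factor 13/8, placed at every
backbone and neck C3 slot: delta +318,972, giving 7.39 M (20 classes)
and 7.55 M (80 classes) exactly.  With a 3x3 group kernel no grid point
lands inside the window (the few real-valued factors that would are
excluded by the divisibility of the hidden width by G), so the
calibrated enhancement is a grouped channel-bottleneck; the spatial
selectivity comes from the local-region gate.  An empty feasible set
raises a calibration error carrying the nearest candidates — never a
silent fallback.  These calibrated values are the shipped
`AttentionSpec` defaults.

## Training harness

Target assignment and loss follow the host family's public convention:
a label matches an anchor when `max(r, 1/r) < 4` for the width/height
ratios `r`, is assigned to its grid cell plus the two nearest
neighbouring cells, and the loss is

    L = 0.05 * mean(1 - CIoU) + 1.0 * BCE_obj + 0.5 * BCE_cls

summed over three scales with objectness balance weights (4.0, 1.0,
0.4), objectness targets equal to the detached CIoU of the decoded
prediction, and the total scaled by the batch size so the per-image
gradient is batch-size independent.  The optimizer is SGD with momentum
0.937, learning rate 0.01, weight decay 5e-4 on convolution weights,
and a linear warmup (50 steps by default).  Defaults mirror the study
conditions: 300 epochs, batch 40, early stopping with patience 100,
640x640 inputs; the best checkpoint is chosen by validation mAP@0.5.
Augmentation is horizontal flip plus mild scale jitter; mosaic
augmentation and anchor re-estimation are deliberately out of scope.

Evaluation decodes raw logits (sigmoid on xy/objectness/class,
anchor-scaled wh), applies greedy per-class NMS, and computes average
precision by greedy highest-score-first one-to-one matching and
101-point interpolation of the precision–recall envelope (precision at
recall r is the maximum precision at any recall >= r).  mAP@0.5:0.95
averages the ten IoU thresholds 0.5 to 0.95.  Evaluation uses a
confidence floor of 0.001, the family's standard for mAP computation.

All tensor computation runs on a small in-repo reverse-mode autodiff
engine over numpy (float32, im2col convolutions through BLAS).  Batch
normalization uses momentum 0.03, so running statistics need on the
order of 150 optimizer steps to track the batch statistics — visible in
short runs as validation mAP lagging the training loss.

## Synthetic fields

The generator emulates the *shape* of the cotton-weed task — 12 object
classes by default, cluttered soil/vegetation backgrounds, one to four
objects per image at 12–35 % of the image diagonal, 640x640 images,
7:2:1 train/val/test split — with procedurally drawn leaf rosettes
(class-specific lobe count and hue).  Labels are derived from the
rendered pixel-ownership mask, so every label box equals the visible
extent of its object exactly and the evaluator's ceiling is known to be
perfect labels.  Identical scene specifications yield byte-identical
datasets.

What the synthetic scenes do *not* emulate: photographic texture,
illumination variation, occlusion by the crop itself, class imbalance,
and intra-class shape variability of real weeds.  Passing tests on
these scenes therefore validate the machinery (assignment, loss,
decoding, NMS, metrics) and the optimization loop, not field accuracy;
the published dataset accuracies require GPU-scale training on real
imagery and are outside this package's scope.

## Problem sizes in the test suite

The suite exercises full-width (0.50) models only for construction and
profiling, which are fast.  Everything that trains or runs many forward
passes uses a narrow (width 0.125) detector on small synthetic scenes:
the overfit benchmark trains 200 full-batch epochs on eight 320x320
scenes with four classes and reaches train-set mAP@0.5 >= 0.9, which is
the package's pinned evidence that the loss, assignment and evaluator
close the loop.  These sizes are the package's own choice of desk-scale
study conditions.

## Known limitations

- Single-threaded numpy training is orders of magnitude slower than a
  GPU framework; the harness is for verification and small studies, not
  production training.
- `MaxPool2d` supports the SPPF configuration (stride 1); the detector
  downsamples with stride-2 convolutions only.
- The FLOP convention prices elementwise work explicitly; comparisons
  against profilers that count only convolutions should use the
  convolution-only convention exposed on `FlopConvention`.
- Letterboxing is not implemented; images are resized square upstream
  of the model (the synthetic scenes are square by construction).
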