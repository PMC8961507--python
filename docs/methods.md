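# Methods

## The architecture family

The package compiles a small notation into encoder–decoder
segmentation networks. One *U structure* `U(d-u)` is a
contract–expand unit: `d` descending levels including the valley and
`u` ascending levels including the terminal layer. Structures are
composed two ways:

* **cascade** (`-`): structures run in series. The layer where one
  expansive path ends and the next contracting path begins is a *peak*;
  with symmetric structures the peak sits at input height (high peak),
  with `U(4-3)-U(3-4)` it sits one level below (low peak). The profile
  of two cascaded U structures is a W.
* **parallel** (`//`): structures run side by side as independently
  initialized branches of one segment, split from a common input and
  fused at their valleys and terminal layers.

Elevation bookkeeping drives validation: the input sits at elevation
0, each pool descends one level, and an architecture is accepted only
if every cascade joint stays at or below input height and the final
elevation is exactly 0 (output at input height). Depths within one
structure may differ by at most one level.

### Block construction rules

With base channel count `f_d` (default 64; tests use 2–4 for speed)
and elevation `−k`:

| role      | operations                                                           |
|-----------|----------------------------------------------------------------------|
| down      | [3×3 conv `f_d·2^k`, BN, ReLU] ×2, 2×2 max-pool                      |
| valley    | [3×3 conv, BN, ReLU] ×2, dropout 0.5, no pool                        |
| up        | 2× upsample, 2×2 conv halving channels, concat skip partner, [3×3 conv, BN, ReLU] ×2 |
| peak      | as *up*, then the next structure's 2×2 pool appended                 |
| terminal  | as *up*, second 3×3 conv replaced by a 1×1 conv                      |
| output head | 3×3 conv → 2 channels, then 1×1 conv → 1 channel, sigmoid         |

Skip connections concatenate the pre-pool feature map of the
equal-elevation contracting layer of the *same* U structure; different
U structures are independent — they touch only through shared peaks,
declared cascade joints and merge nodes. The compiler's `validate()`
enforces this, and the shape-inference pass recomputes every
resolution and channel count from the op schedule rather than from a
closed form.

Two deliberately resolved ambiguities:

* **Peak semantics.** The operational schedule treats the peak block
  as upsample/concat/two convs followed by the next structure's pool.
  In addition, a flag `peak_to_output_concat` (default on)
  concatenates each high peak's pre-pool features into the output
  head, realizing the reading in which the output is the cascade of
  the output layer and the peak layer. Low peaks (elevation −1) are
  *not* concatenated: their resolution is half the output's, so a
  channel-axis concatenation is undefined. The extra edge has its own
  kind (`peak_concat`) so skip-edge invariants stay exact.
* **Up-layer op order.** Upsampling precedes the 2×2 convolution; the
  reverse order cannot reproduce the published channel schedule.

Degenerate and asymmetric cases: a depth-1 structure is a pool-less
two-convolution block doubling as its own valley; a raised-exit
structure such as `U(3-4)` has no same-elevation contracting partner
for its top layer, which therefore carries no skip edge. A cascade
joint can only share a peak block when both adjacent segments are
single-branch and the preceding terminal is a genuine up block;
otherwise the joint is an explicit forward edge (and, for parallel
segments, a merge node).

### Parallel branches

A segment with `b > 1` branches begins with a split node fanning the
input to `b` independently parameterized chains. Fusion ("convergence")
is channel-axis concatenation followed by one 3×3 convolution restoring
the nominal channel count, applied at the branch valleys — the fused
valley tensor feeds *every* branch's expansive path — and at the branch
terminal layers, whose fused output feeds the next segment or the
output head. Branch independence at initialization comes from
per-convolution seed streams (seed, conv index), so two branches of the
same shape receive different initial weights while the whole model
remains a pure function of one seed. Heterogeneous branch depths within
a group are accepted only behind an explicit flag and must share the
same net elevation change; valley fusion then applies per
equal-elevation subset.

## Numeric backend

No deep-learning framework is part of the package's dependency
surface; the backend is a compact numpy implementation in `eunet.nn`:
tap-gathered 'same'-padding convolutions (dilation supported, even
kernels pad bottom/right), 2×2 max-pooling with first-index tie-breaks,
nearest-neighbour upsampling, batch normalization (ε = 1e-3, running
momentum 0.9, statistics over N·H·W), inverted dropout, ReLU/sigmoid,
and reverse-mode gradients driven over the compiled op program in fixed
topological order. Tensors are NHWC float32; the loss and its gradient
are accumulated in float64. Optimizers: Adam (β₁ = 0.9, β₂ = 0.999,
ε = 1e-7) and SGD with momentum. Correctness is established by central
finite differences per op and by a whole-network directional-derivative
test (biases shifted off the ReLU/pool kinks, where the loss is
legitimately non-differentiable and a subgradient is used).

Determinism: parameter initialization, shuffling and dropout each draw
from separate seed-derived streams; with `deterministic_mode` (the
default) a rerun with the same seed, data and configuration reproduces
the loss trace bit for bit.

## Training and evaluation

Training minimizes the soft Dice loss
`1 − (2Σpt + ε)/(Σp + Σt + ε)` with ε = 1 pooled over the batch.
Defaults: Adam at learning rate 1e-3, batch size 4, explicit
train/test file lists (never a random split at train time). Two loss
traces are recorded per epoch: the optimisation-time batch mean
(dropout active, batch statistics) and the evaluation-mode loss on the
training set (dropout off, running statistics) — the latter is the
model's actual fit and is what early stopping (`stop_at_train_loss`)
and the capacity tests read. An optional per-epoch validation loss and
metric report complete the trace.

Metrics: accuracy, precision, specificity, and mIoU defined as the
two-class mean of foreground and background IoU — the background IoU
uses TN/(TN+FN+FP). All are percentages of exact pixel tallies; a
zero-denominator ratio is reported as undefined (`NA`), never as zero.
Dataset evaluation is micro-averaged (counts pooled over all pixels)
by default, with macro (per-image mean) available. Probability maps
are binarized at 0.5.

### Problem sizes used by the test suite

The capacity checks run every named variant (SHP, DHP, THP, U\*UNet,
U\*U\*UNet) at `f_d = 4` on 32×32 inputs against four seeded cell
phantoms, with batch size 2, learning rate 1e-2 and a 500-epoch cap,
stopping once the evaluation-mode training loss reaches 0.05. The
elevated learning rate is the memorization-protocol choice for this
deliberately tiny configuration (a few tens of thousands of
parameters, two optimisation steps per epoch); the library default for
real training remains 1e-3. The comparison workflow check uses a
40-image 32×32 vessel set under one shared 5-epoch protocol — it
verifies the harness end to end, not segmentation quality.

## Synthetic phantoms

Two seeded generators stand in for the two kinds of evaluation
imagery; both are fully reproducible (same configuration ⇒ identical
bits) and every mask is guaranteed non-empty.

* **cell** mode emulates low-resolution in-vivo microscopy of cells:
  3–7 soft-edged elliptical blobs (half-maximum exactly on the ellipse
  boundary, so the mask is the thresholded blob field), multiplicative
  smooth texture (strength 0.15), additive Gaussian noise
  (σ = 0.04). Default 90 images of 128×128 with a 60/30 train/test
  split. The set-level mean foreground fraction is asserted to lie in
  a configurable band (default 5–40 %).
* **vessel** mode emulates retinal vasculature: 2–5 smooth random-walk
  tracks dilated to widths 1–4 px, bright on a textured darker
  background, mask = exact track support. Default 40 images with a
  20/20 split; real fundus images (e.g. 584×565 TIFFs) are supported
  by the loader, which reversibly reflect-pads to the
  pooling-divisible size (584×565 at five levels pads to 592×576) and
  crops predictions back.

What the phantoms do *not* model: anisotropic microscope PSFs,
intensity inhomogeneity across the field, vessel branching topology and
calibre hierarchies, inter-observer mask ambiguity, and class imbalance
as extreme as real fundus data. Passing the phantom-based tests
therefore demonstrates that the architectures, gradients and protocol
work — not that any variant ranks above another on real clinical data;
benchmark-scale claims on the real datasets require the original
imagery and GPU-scale training, and the published training
hyperparameters for those tables are not stated, so the training
configuration is exposed rather than hard-coded.

## Known limitations

* The backend is CPU/numpy: ideal for desk-scale, deterministic
  experiments; not for 584×565 × hundreds-of-epochs workloads.
* Max-pool tie-breaking and ReLU kinks make the loss piecewise smooth;
  gradient checks avoid the kinks and optimization uses subgradients,
  as everywhere in the field.
* Batch-norm evaluation mode trails training mode until the running
  moments converge (momentum 0.9 ⇒ a few dozen steps).
* The nested-dense-skip comparison network and deep supervision are
  out of scope; the comparison harness can rank any set of notations
  it can compile, and external baselines must be brought by the user.
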