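# Methods

This note records the model as implemented, the parameters that matter, the
numerical conventions, and what the synthetic test bed does and does not
show.

## Model

The network is an encoder–decoder (U-Net topology) for binary polyp
segmentation with three edge-oriented components.

**Learnable Canny kernel (ConvLCK).** Classical Canny edge detection is a
Gaussian smoothing, a Sobel gradient pair, non-maximum suppression, and
hysteresis thresholding.  The last two stages are non-differentiable, so the
operator used inside the network keeps only the differentiable half and
makes it trainable: a 5×5 smoothing kernel initialised to a normalised
discrete Gaussian (σ = 1 by default), two 3×3 gradient kernels initialised
to Sobel x/y, and the per-pixel magnitude √(Gx² + Gy² + ε) with ε = 1e−8 so
the gradient is defined at zero response.  The operator is depthwise — one
shared kernel set applied to every channel — which keeps it
channel-count-agnostic and channel-permutation-equivariant.  Spatial padding
is mirror ("reflect-101", with edge replication for degenerate 1-pixel
axes) so the output has the input's shape and no artificial border edges
appear.  Per-channel distinct kernels and a learned threshold surrogate are
deliberately out of scope.

**Covariance edge-enhanced attention (CEEA).** Given features
F_in ∈ R^{C×H×W} and their edge response F_e = ConvLCK(F_in), both maps are
channel-centred and flattened row-major to C×HW.  Two attention maps are
formed with the biased 1/HW covariance normalisation:

* channel attention A_c = softmax_rows((1/HW)·F_in″·F_e″ᵀ) ∈ R^{C×C};
* position attention A_p = softmax_rows((1/HW)·F_e″ᵀ·F_in″) ∈ R^{HW×HW}.

How the two maps refine F_in is an open design point; this implementation
uses a dual-branch gated residual,

    F_out = F_in + γ_c·unflatten(A_c·F_in″) + γ_p·unflatten(F_in″·A_pᵀ),

with scalar gates γ_c, γ_p learnable and initialised to zero.  Rationale:
both branches are dimensionally consistent (C×HW), the module is an exact
identity at initialisation (which stabilises early training and makes the
"plain network" limit testable), and gated residual fusion mirrors
established dual-attention practice.  A_p's orientation is a convention:
row i weights source positions j, and the branch multiplies by A_pᵀ on the
right so output position i aggregates with row-i weights.

**Position-attention cost cap.** A_p has (HW)² entries, which is unusable at
encoder resolution (256² pixels → 4×10⁹ entries).  When HW exceeds
`spatial_cap` (default 1024, i.e. a 32×32 token grid) the two maps are
adaptively average-pooled — halving the grid until it fits — the position
branch is computed at pooled resolution, and its output is bilinearly
upsampled before gating.  1024 tokens keeps the attention map at ~1M
entries, small enough that a whole training step of the small CPU
configuration stays under a second in double precision; the cap is
configurable per network.

**Cross-scale edge enhancement (CSEE).** At each skip connection the decoder
stream is first aligned to the encoder stream (bilinear resize + 1×1
channel projection, identity-initialised when the channel counts already
match; alignment is plumbing, not part of the module).  Both aligned maps
pass through one *shared* ConvLCK — a single instance serves every skip
level of the network, which the depthwise design makes possible — and a
channel attention A_csee = softmax_rows((1/HW)·F″_e,enc·(F″_e,dec)ᵀ)
reweights the encoder's edge channels by their covariance with the
decoder's.  Fusion is

    F_csee = F_dec + F_enc + γ_s·unflatten(A_csee·F″_e,enc),

with γ_s zero-initialised, so the skip starts as the plain additive U-Net
skip.  The attended term enriches the encoder stream (it is the stream that
carries fine boundary detail); this is a convention, recorded as such.  No
position branch is used at the skips — the cross-scale comparison is
channel-wise only.

**Backbone.** Stage widths default to (32, 64, 128, 256, 512) with two
convolution blocks (3×3 mirror-padded conv → batch norm → ReLU) per stage,
an attention module after each encoder stage, 2× max-pool downsampling, and
a mirrored decoder with 2× bilinear upsampling.  Depth and widths are a free
design choice pinned to the conventional U-Net scale; tests and the
acceptance script use scaled-down widths so everything runs on one CPU.  The
head is a 1×1 convolution to two classes followed by a pixel-wise softmax.
Batch norm uses batch statistics in training and running averages
(momentum 0.1) at inference.

**Ablation switchboard.** The attention slot accepts `ceea`, `conv` (one
extra convolution block), `self` (single-head scaled dot-product
self-attention over pooled tokens with Q/K/V/out 1×1 projections and a
residual connection), or `none` (plain U-Net counterpart); `use_csee=False`
replaces every skip fusion with plain addition and removes the module's
parameters.  Parameter initialisation is seeded per module path, so two
configurations sharing a sub-module initialise it identically — this is what
makes the zero-gate identity between the full network and its plain
counterpart exact.  Note the parameter-count ordering that follows from
these designs: the covariance attention adds only ~45 parameters per stage
(the shared kernel set plus two gates), self-attention ~4c², and the extra
convolution block ~9c².

## Loss

    L_hybrid = α·L_CE + β·L_edge,    α = β = 0.5 by default.

L_CE is −(1/HW)·Σ_{i,j}Σ_c Y log P on softmax probabilities clamped at
1e−7 (the printed normalisation is by pixel count only; batches are
additionally averaged over N).  L_edge compares edge maps of the foreground
planes of P and Y.  The comparison functional is not pinned down by the
published description, so the implementation uses the mean absolute
difference of Sobel gradient magnitudes — robust for sparse boundary maps
and on the same scale as L_CE.  Edge(·) inside the loss is the *fixed*
Sobel operator, not the learnable kernel: a learnable loss target could
collapse to zero edges, and the loss must be a fixed yardstick.  In the
differentiable path the magnitude carries a 1e−12 stabiliser so its
gradient is finite on flat regions.

There is an internal tension in the published protocol between a hybrid
loss and a plain cross-entropy setting; both are exposed
(`loss_mode="hybrid" | "ce"`), hybrid being the default.

## Training protocol

SGD with momentum 0.9; polynomial decay lr(t) = lr0·(1 − t/T)^0.9 applied
per iteration (per-iteration rather than per-epoch for a smoother schedule;
the 0.9 exponent is the conventional "poly" power and is configurable).
Default lr0 = 0.002 (the tabulated value; the alternative 0.02 that appears
in the same source is reachable via config), batch 64, 256×256 random
crops with horizontal/vertical flips, up to 500 epochs, model selection by
the lowest validation loss computed with the same loss mode.  Augmentation
can be disabled (`augment_train=False`) for pure memorisation checks, where
fitting the four flip variants of every image is not the point.  With a
fixed seed and thread count the loss history is bitwise reproducible.

## Metrics

Dice, IoU, sensitivity and specificity are exact rational functions of the
pixel confusion counts; per-image values are averaged unweighted over the
test set (per-image mean, not pixel pooling — the field's convention for
mDice/mIoU).  Degenerate conventions: empty ground truth and empty
prediction score 1.0; empty ground truth with a non-empty prediction scores
0 through TP = 0.

## Synthetic phantoms

The generator reproduces the two properties that make colonoscopic lesions
hard — a small lesion/mucosa intensity gap and soft boundaries — with exact
ground truth: a smooth low-frequency background field (four random
sinusoids normalised into [0.35, 0.65]) plus optional Gaussian speckle
(σ = 0.04 per unit of `texture_strength`); each lesion a random rotated
ellipse with axes 5–25% of the short image side, rendered at
background ± contrast (channel-weighted 1.0/0.85/0.75 so the gap is
strongest in red, as on mucosa), its rim blurred by `boundary_softness`
pixels; the mask is the union of unblurred ellipse interiors.  Everything
is drawn from one integer-seeded generator, so samples are bit-identical
across runs and platforms.

What the phantoms do *not* model: specular highlights, instruments, motion
blur, vignetting, colour variability of real mucosa, and non-elliptical
lesion geometry.  Passing the phantom-based tests therefore demonstrates
that the architecture, loss, optimiser and metrics are implemented
correctly and that the network can learn low-contrast boundaries — it says
nothing quantitative about performance on real colonoscopy benchmarks,
which require external data and long GPU training.

## Problem sizes used in tests and the acceptance script

Oracle and property checks run on maps up to 4×4×4 (where brute-force loop
references are exact and fast).  The capacity check trains the
(8, 16, 32)-width network on eight 64×64 phantoms at contrast 0.5 for 300
iterations (batch 4, lr0 = 0.01, the decay schedule spanning the full
500-epoch run with a hard stop at 300 steps, flips off) — a pure
memorisation protocol whose success criterion is mean training Dice ≥ 0.95
— and evaluates the two held-out phantoms.  Determinism is checked on a
(4, 8)-width network at 32×32.  These sizes are the package's chosen desk
scale: small enough for a single CPU in double precision, large enough that
every module (attention pooling included) is exercised on its real code
path.

## Known limitations

* The covariance/attention stack is quadratic in the token count; the cap
  trades spatial attention resolution for memory and time.
* Batch norm with very small batches (1–2) uses noisy statistics; the toy
  configurations use batch ≥ 2 and full-image patches.
* The refinement formulas (how attention maps recombine with features, and
  which stream the cross-scale term enriches) are design choices at points
  the published description leaves open; they are recorded above and
  guarded by tests, but other choices are defensible.
* Checkpoints store raw float64 weights with the architecture config
  embedded; no quantisation or pruning.
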