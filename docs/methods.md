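# Methods

## The model

`wmtseg` implements binary segmentation of single-channel medical-style
images with a transformer whose attention is *axial* and *gated*, wrapped
in a U-Net encoder–decoder and a coarse/fine patch-fusion head.

### Attention operators

For a feature map `x ∈ R^{C_in×H×W}` with learned projections
`q = W_Q x`, `k = W_K x`, `v = W_V x` (`W ∈ R^{C_out×C_in}`):

* **Full self-attention.** Every output position is a softmax-weighted
  combination of the value vectors at all H·W positions,
  `y_ij = Σ_hw softmax(q_ijᵀ k_hw) v_hw`.  Cost grows with (HW)², which is
  why it never appears in the network itself; it exists as the reference
  the axial operators are reduced from and tested against.
* **Axial attention.** Attention restricted to one row (width axis) or one
  column (height axis), with additive relative positional encodings:
  `y_ij = Σ_w softmax(q_ijᵀ k_iw + q_ijᵀ r^Q_jw + k_iwᵀ r^K_jw)(v_iw + r^V_jw)`.
  A height pass followed by a width pass covers the full map at cost
  H + W keys per position instead of H·W.
* **Weighted (gated) axial attention.** Four learnable scalars gate the
  positional and value terms:
  `y_ij = Σ_w softmax(q_ijᵀ k_iw + C_Q q_ijᵀ r^Q_jw + C_K k_iwᵀ r^K_jw)(C_V1 v_iw + C_V2 r^V_jw)`.
  The motivation is small datasets: relative positional encodings learned
  from little data can be unreliable, and the gates let the network learn
  to discount them.  Gates initialize to 1.0 so training starts exactly at
  ungated behaviour.

**Positional-table dimensionality.** The tables are per-pair *vectors* with
the same channel dimension as q/k/v; the logit terms are inner products.
This is the only reading under which the logit and payload terms are
dimensionally consistent (a scalar-per-pair table could enter the logits
but could not be added to the value vector).  By default the tables are
parameterized by relative displacement (2L−1 learnable vectors expanded to
the L×L pairwise table), making the encodings translation-shared;
`relative_tables=False` switches to a free L×L table.

**Choices the formulas leave open.**  Logits are *not* scaled by 1/√d —
the operator definitions above have no scaling term — but a
`logit_scaling` flag provides the conventional scaling.  Attention is
single-head by default (`heads` splits C_out evenly when raised).  The
height pass is the exact transpose-symmetric analog of the width pass, and
the two passes of a 2-D layer own separate projections and positional
tables.  Softmax subtracts the per-position logit maximum before
exponentiation (exactly invariant, numerically safe).

**Degenerate inputs.**  When an attended axis has length 1, softmax over a
single key is identically 1 for any logits; the output reduces to
`C_V1·v + C_V2·r^V` and the logit parameters (`W_Q`, `W_K`, `r^Q`, `r^K`,
`C_Q`, `C_K`) receive exactly zero gradient.  This is correct behaviour,
not a bug; architectures should avoid pooling attention maps down to 1×1
if those parameters are supposed to train.

### Architecture

The backbone is a U-Net: `depth` encoder levels (channel widths
`base·2^l`), 2×2 average pooling between levels, a bottleneck, and a
convolutional decoder (nearest-neighbour upsampling, skip concatenation,
double 3×3 convolution).  In the attention variants, the encoder blocks
and the bottleneck use a 2-D axial attention layer followed by a 1×1
convolution; the decoder stays convolutional, since only the encoder is
attention-based in this design.

The dual-branch head partitions the I×I input into 4 coarse blocks (side
I/2) and 16 fine blocks (side I/4).  Each block runs *independently*
through a branch-specific full encoder–decoder backbone (no cross-block
state inside a branch — inter-block information enters only through the
coarse branch's larger receptive field), block outputs are reassembled at
their recorded origins, the two branch maps (both `base` channels) are
summed, and a 1×1 convolution produces single-channel logits; the
probability map is its sigmoid.  Branch backbones have independent weights
by default (`share_branch_weights` enables sharing for the convolutional
backbone; attention backbones cannot share because positional tables are
bound to the block side).

Five variants build from one config and form the ablation ladder:
`unet`, `unet_axial`, `unet_weighted_axial`, `unet_coarse_fine`, `wmt`
(gated axial encoder + dual branch).  At equal depth/width the parameter
counts are strictly ordered
`unet_axial < unet_weighted_axial < unet < wmt < unet_coarse_fine`:
an axial layer (three C_out×C_in projections + three (2L−1)-vector tables
per pass) is lighter than a double 3×3 convolution at these widths, and a
dual branch roughly doubles a backbone.

### Training

Loss is mean pixelwise binary cross-entropy,
`L = −(1/wh) Σ [p log p̂ + (1−p) log(1−p̂)]`, with `p̂` clamped to
`[ε, 1−ε]`, `ε = 1e-7`, so the logarithms stay finite.  The reference
configuration is 400 epochs at initial learning rate 1e-3 with a
decaying schedule; the decay form is a package choice (cosine to zero by
default, with `step` and `constant` options).  The optimizer is Adam with
default betas (`sgd` available).  Batch size defaults to 4; the
segmentation threshold for mask output is 0.5.

For *overfit sanity checks* (can the model memorize a handful of images?)
the package uses the constant schedule at the same 1e-3: annealing the
rate to zero is a generalization device and only slows memorization, which
is the quantity such a check measures.

### Evaluation

F1 = 2·Prec·Rec/(Prec+Rec) (the Dice coefficient), IoU = TP/(TP+FP+FN),
accuracy = (TP+TN)/total, all from one confusion-count pass.  The identity
IoU = F1/(2−F1) holds for any counts and is property-tested.  When both
masks are empty, F1 = IoU = 1.0 by convention (documented and test-pinned).
Dataset-level scores are macro-averaged (per image, then mean) by default;
`micro` pools confusion counts first.  Which convention published tables
use is generally unstated, so both are exposed.

## Synthetic phantoms

The generator emulates the two data regimes the method targets without
requiring any download:

* **organ** — one large foreground region with a smooth closed boundary
  (liver-like): a periodic cubic spline through `boundary_smoothness`
  random control radii around a random center, filled as a star-convex
  polygon.  Exactly one connected component per mask by construction.
* **nuclei** — many small non-touching elliptical blobs (stained-nuclei
  like), rejection-sampled with a 2-px exclusion margin; infeasible
  packing densities raise an error suggesting parameter changes.

Images are mask-driven: base intensity 0.35, plus a smooth random texture
confined to the background (zero-mean there, amplitude bounded by
`texture_amp·contrast/2` with `texture_amp = 0.3` so the foreground/
background separation is never ambiguous), plus `contrast = 0.45` on the
foreground, plus i.i.d. Gaussian noise (`noise_sd = 0.03`).  Consequences
used by the tests: with zero noise, thresholding at base + contrast/2
recovers the mask exactly; with noise, the foreground−background mean gap
equals `contrast` up to noise-of-the-mean terms.

**What the phantoms do not emulate:** CT physics (Hounsfield calibration,
beam hardening), anatomical context around the organ, staining variability
and touching/overlapping nuclei, annotation noise.  Passing tests on
phantoms therefore demonstrate that the operators, architecture, and
optimization behave as specified — not that the model reaches any
particular accuracy on real liver CT or histology data.

## Problem sizes

The test suite and the acceptance script run everything at desk scale on
one CPU, a deliberate package choice so the whole pipeline is exercised in
minutes: operator/oracle checks at H, W ≤ 8, C ≤ 4; the learning check as
a 4-phantom overfit fixture (wmt, input side 32, depth 2, base 8 channels,
200 epochs, constant 1e-3) reaching loss < 0.05 and IoU > 0.9; the
ablation harness at side 16 with reduced epochs, where only the table
structure — five rungs in ladder order — is meaningful, not the scores.
Published full-scale scores (e.g. F1 ≈ 88%, IoU ≈ 79% on a 420-image liver
CT set) require the real datasets and hundreds of GPU epochs and are out
of scope for this artifact.

## Known limitations

* The autodiff core is minimal by design: float64, CPU, stride-1
  convolutions, 2×2 pooling/upsampling only.  It is not a performance
  engine; at the reference scale (512-pixel preprocessing, 128-pixel
  inputs, 400 epochs) training would be impractically slow compared to a
  GPU framework.
* Single-channel input and binary masks only; no augmentation, mixed
  precision, or distributed training.
* Attention backbones fix the input side at build time (positional tables
  are size-bound); a checkpoint only applies to its recorded geometry.
* The coarse/fine branches are trained jointly on all images.  Schemes
  that train the branches on disjoint image subsets are not implemented —
  it is unclear how such a split would map onto a single jointly-fused
  model, and joint training is the natural reading of the fused
  architecture.
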