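# Methods

## The model

`medcss` trains a 3-D convolutional classifier for small volumetric
medical images (e.g. 28³ CT nodule crops) with two auxiliary objectives
that act on the encoder's feature hierarchy rather than on its outputs.

### Backbone

The encoder is a 3-D ResNet with squeeze-and-excitation (SE) channel
attention: a 7×7×7 stride-2 stem convolution, group normalization, ReLU
and a 3×3×3 stride-2 max-pool, followed by four residual stages. Depth 10
uses one basic block per stage, depth 18 two, depth 50 bottleneck blocks
in the classic (3, 4, 6, 3) layout with expansion 4. The SE gate sits on
the residual branch after its last normalization, before the skip
addition — the standard SE-ResNet placement — and squeezes each channel
to its spatial mean, passes it through a two-layer bottleneck MLP
(reduction ratio `se_reduction`, hidden width clamped to ≥ 1), and
rescales the channels by the resulting sigmoid weights. Setting
`se_enabled=False` bypasses every gate, which recovers a plain residual
network exactly (tested against saturated gates).

Two tap points expose the hierarchy: `f3`, the stage-3 activation map
(mid-level morphology), and `f4`, the stage-4 map (global semantics).
Global average pooling gives `z3`, `z4`; two separate two-layer
projection heads (linear → ReLU → linear, hidden width = `proj_dim`) map
them into a shared latent space as `h3`, `h4`. The prediction head is a
single affine map on `z4` with a sigmoid (binary) or softmax (multiclass)
output; for the binary task the positive-class score is the sigmoid of
the last logit column.

Design choices made where the architecture was genuinely open:

* **Normalization.** Group norm (largest divisor of the channel count
  ≤ 8 groups) instead of batch norm: no running statistics, forward
  passes are bit-stable, independent of batch composition, and
  well-defined for single-sample batches. This matters because model
  selection, probe measurements and determinism checks all rely on
  exactly reproducible inference.
* **Tap points.** Stages 3 and 4 at every depth, including depth 10,
  since the early stages carry low-level texture and the late stages the
  semantics the alignment loss is meant to couple.
* **Adaptive downsampling.** A stage whose incoming map is already a
  single voxel keeps stride 1, so any input of side ≥ 8 reaches the
  prediction head; 16³ and 28³ volumes both work unchanged.
* **Initialization.** He fan-out for convolutions; the final norm scale
  of every residual branch starts at zero so each block begins as an
  identity map; the whole parameter tree is a function of one seed.
* **Width.** `base_width` (stage-1 channels; stages double it) defaults
  to 16. That is deliberately narrower than the classic 64: the package
  targets CPU-scale volumes, and on the phantom tasks the narrow model is
  already strongly over-parameterized. 64 restores the textbook layout.

### The two regularizers

**Coding-rate reduction (CRR).** For a pooled feature batch
`F ∈ R^{B×d}` with population covariance `Σ = (1/B)(F−F̄)ᵀ(F−F̄)`, the
coding rate

    R(F) = ½ log det(I + α Σ)

measures the log-volume of the batch's covariance ellipsoid — a smooth
proxy for feature redundancy, with `α` (default 1.0) setting the
sensitivity to variance. The causal-compression prior says deeper
features should be *more* compressed than intermediate ones, so the
penalty is the hinge

    L_crr = max(0, R(z3) − R(z4)),

zero whenever the hierarchy already compresses. The hinge operates on the
pooled `z3`/`z4` (shape B×d); flattening the raw 5-D maps would make the
covariance enormous and rank-deficient. `R` is computed from a Cholesky
factorization of `I + αΣ + jitter·I` (jitter 1e-6), never from a raw
determinant; when `d > B` the dual B×B Gram form is used — both forms
share their non-unit eigenvalues, so the value is identical (tested to
1e-6) and the cost is bounded by min(B, d)³.

**JS alignment.** The projections `h3`, `h4` are each reduced to one
empirical categorical distribution: a per-sample softmax over the
`proj_dim` coordinates, averaged over the batch. The alignment loss is
the Jensen–Shannon divergence between the two distributions, in base-2
logs so it is bounded by 1 bit, with 1e-12 smoothing inside the logs.
This construction was chosen because it is differentiable, robust to
batch size, bounded, and invariant to row order. By default it is
computed on the single forward pass of the augmented batch; the
`align_across_views` flag instead aligns `h3` of one augmented view with
`h4` of a second, independently augmented view.

**Joint objective.**

    L_total = L_sup + λ_align · L_align + λ_crr · L_crr

with weighted cross-entropy as `L_sup` (class weights default to inverse
training-class frequency, weight-normalized so uniform weights reproduce
the unweighted mean exactly). Defaults λ_align = 0.1, λ_crr = 0.01 put
the auxiliary terms roughly one and two orders of magnitude below the
task loss at initialization; both are config keys. The ablation variants
force the weights: baseline (both 0), naive_align (λ_crr = 0), cr_only
(λ_align = 0), full (both as configured).

### Training loop

Each step draws `batch_size` indices with replacement from the
inverse-class-frequency sampler (`p_i ∝ 1/n_{c_i}`, so expected sampled
mass is equal across classes), augments every volume, and takes one Adam
step (lr 1e-3, β = 0.9/0.999, no schedule) on `L_total`. An epoch is
⌈N/batch⌉ steps; the default budget is 50 epochs (the end-to-end tests
use 8). Model selection keeps the weights with the best validation AUC.
Every epoch also records `R(z3)` and `R(z4)` on a fixed probe batch (the
first ≤ 32 training volumes, un-augmented), so the hinge gap is traceable
over training. Gradients come from reverse-mode autodiff over the pure
numpy forward pass; the only custom vector-Jacobian product is the
col2im scatter-add behind the im2col convolution primitive. Everything —
init, sampling, augmentation — derives from `TrainConfig.seed`, so a rerun
with an identical config reproduces the loss trajectory exactly on a
single CPU thread.

Augmentation is dual-domain: spatial (per-axis mirror flips p = 0.5,
90° rotations p = 0.5, integer shifts ≤ 2 voxels with edge padding) and
photometric (multiplicative jitter in [0.9, 1.1], additive shift in
[−0.05, 0.05], Gaussian noise sd 0.01), output clipped to [0, 1]. All
transforms preserve the label and the structural topology. At validation
and test time the only transform is the linear intensity rescale to
[0, 1] applied at load time.

## The phantom generator

The generator emulates the *task structure* of three volumetric
benchmark families, not their image statistics:

* **nodule** — class 0 a smooth sphere of radius 2–4 voxels, class 1 a
  larger (4–6) sphere whose surface radius is modulated sinusoidally over
  the direction angles (spiculation);
* **vessel** — a quadratic-Bézier tube of radius 1–2 voxels entering and
  leaving through opposite faces; class 1 adds a spherical bulge of 2–3×
  the tube radius on the tube path. Both labels consume identical random
  draws before the bulge, so matched seeds give the same tube and the
  class difference is exactly the malformation;
* **synapse** — class 0 one Gaussian blob, class 1 two partially
  overlapping blobs (center distance 1.5–2.5 σ).

Foreground intensity is drawn in [0.6, 1.0] on a 0.05 background, then
Gaussian blur (default σ 0.5 voxels) and additive noise (default sd 0.02)
are applied and the volume is clipped to [0, 1]. Splits are 70/15/15;
the training split follows `positive_fraction` (default 0.11, mirroring
the minority-positive regime of vessel-malformation screening) while
val/test are balanced 50/50 so threshold metrics stay interpretable.
Datasets are written in the MedMNIST3D NPZ dialect (uint8 volumes,
(N, 1) label columns) with a JSON sidecar recording the spec, and a real
MedMNIST3D file passes through the same reader interchangeably.

What passing tests on phantoms do and do not show: the phantom classes
are separable by total foreground volume (a threshold classifier reaches
AUC ≥ 0.9; asserted), so end-to-end tests demonstrate that the losses,
sampler, optimizer and metrics interact correctly and that training
converges on a solvable task — they do not certify performance on real
CT/MRA distributions, where texture, acquisition artifacts and anatomy
dominate.

## Evaluation

Threshold metrics (accuracy, recall, F1) are reported at 0.5, positive
class = label 1, ties at the threshold predicted positive; recall with no
positives present is reported as 0 and flagged. AUC is the Mann–Whitney
pairwise statistic computed from average ranks (ties count ½) and is
required — and tested — to match the trapezoidal area under the ROC
staircase to 1e-9. Probability histograms use 20 equal-width bins on
[0, 1] per class plus a separation summary (absolute difference of
class-conditional mean scores). Transfer evaluation applies a frozen
model to another dataset's test split and reports accuracy at 0.5 only.
The backbone and supervised loss support multiclass heads (softmax,
multiclass cross-entropy), but the metric report is binary; the shipped
tasks are all binary.

## Problem sizes

The end-to-end checks use vessel phantoms with n = 400, side 16,
positive fraction 0.11, a depth-10/width-16 backbone, 8 epochs, batch 16,
and three seeds, with the qualitative assertions (full-variant AUC,
hinge-gap decrease, full ≥ baseline ordering) required in at least 2 of
3 seeds; these sizes are the package's reference configuration for
CPU-scale experiments. The transfer comparison trains on nodule phantoms
(n = 240, 5 epochs) and evaluates frozen on vessel phantoms.

## Known limitations

* Phantoms are separable by construction; margins on real data will be
  smaller, and the default λ's may need retuning there.
* The coding-rate hinge compares `R(z3)` and `R(z4)` raw by default even
  though z3 and z4 have different dimensions; `crr_loss(..., per_dim=True)`
  divides each rate by its dimension first, but the training loop uses the
  raw comparison.
* Single-view alignment is the default; the two-view variant doubles the
  forward cost and is off unless requested.
* CPU-only: the autodiff stack is numpy-based and single-threaded;
  training beyond a few hundred small volumes per run is slow by design
  tradeoff.
* Dice loss (sometimes used for heavily imbalanced tasks) is not
  implemented; the tasks here are whole-volume classification and use
  weighted cross-entropy.
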