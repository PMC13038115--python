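# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the conventions behind the cost accounting, what
the synthetic phantoms do and do not emulate, and the design decisions
taken where the architecture family leaves details open.

## Architecture

The network is a U-shaped hierarchy over token grids.  Patch embedding maps
a 3-channel volume to a `(D/2, H/4, W/4)` grid of `C`-dimensional tokens
(default `C = 96`) by a linear projection of each `(2×4×4)` patch.  Stages
operate at channels `C, 2C, 4C, 8C`; each patch-merging layer concatenates
`2×2×2` neighbors (8C′ features) and reduces them linearly to 2C′, halving
every spatial extent; patch expansion inverts this with a linear `C′ → 4C′`
map redistributed over the `2×2×2` child block (channels halve).  Skip
fusion concatenates decoder and encoder features at equal resolution and
reduces `2C′ → C′` linearly.  A final expansion by the full patch size
restores voxel resolution before a per-voxel linear classifier over the
four classes (background, NCR/NET, edema, enhancing), decoded by argmax.

### Attention

Window attention restricts multi-head self-attention to non-overlapping
windows of `N = p_D·p_H·p_W` tokens with a learned relative-position bias
table of `(2p_D−1)(2p_H−1)(2p_W−1)` entries per head, indexed by the offset
between token positions.  Dilated-window attention selects every `r`-th
token per axis within an `M = r·p` span; the `r³` residue classes of each
span tile the grid exactly once, so every token attends exactly once per
layer and windows keep the same token count `N` while the receptive field
grows by `r` per axis.  With `r = 1` the dilated partition degenerates to
the standard one (verified by test).  Sub-blocks alternate strictly:
window attention first, dilated second, each pre-norm with a 4× GELU MLP
and two residual connections.

The position encoding is a per-channel (depthwise) 3×3×3 convolution of the
feature map added back residually, applied once ahead of each
window/dilated pair.  It runs at native resolution; the resize hooks around
the convolution are identities by default and exposed in `DIPE` for a
coarser encoding grid.

### Depth configuration

Encoder stages use `[2, 2, 6]` attention sub-blocks and the bottleneck two
alternating-pair blocks (four attention layers), per the published block
inventory.  The decoder's sub-block depths are not published; this
implementation defaults to `[1, 2, 4]` (coarse→fine), the setting whose
analytic budget reproduces the published figures of the reference model —
50.33 M parameters (published 50.56 M) and 114.0 G MACs at a 128³ input
(published 115.51 G).  A mirrored decoder (`[6, 2, 2]`) was ruled out: it
yields 44.8 M / 103.9 G, irreconcilable with both published numbers.  Depths
are ordinary config fields; nothing in the implementation assumes evenness
(an odd depth simply ends after a window sub-block).

### Geometry, padding, clamping

The window size defaults to 8×8 tokens in-plane and 2 along depth,
complementing the anisotropic `(2,4,4)` patch that leaves the depth axis
token-densest.  Windows and dilation factors are clamped per stage against
the token grid of `ModelConfig.ref_extents` (default 128³) at construction
time, which fixes the parameter count independently of the runtime input
size.  At runtime, grids that do not tile evenly are zero-padded up to the
window (or dilated-span) multiple, padded key slots are masked out of the
softmax (additive −10⁹), and outputs are cropped back; `pad_policy =
"strict"` raises instead.  Inputs whose extents are not multiples of the
total ×(16,32,32) reduction are likewise padded and cropped, so `forward`
preserves arbitrary extents.

## Cost accounting

`count_parameters` enumerates the constructor's layer inventory
analytically and matches the instantiated model scalar-for-scalar (tested).
`count_flops` charges one FLOP per multiply-accumulate: linear and
depthwise-conv layers cost `in_features × out_features` per output element,
attention layers cost `4ΩC² + 2NΩC` (Q/K/V + output projections plus the
score and value matmuls) on the window-padded token count of their stage.
Layer normalization, softmax, GELU and bias additions are excluded from the
convention; it is recorded in every `CostReport`.  The dense-attention
reference `4ΩC² + 2Ω²C` is exposed alongside for comparison.  Under this
convention the per-volume count is exactly linear in the input volume for
fixed configuration, and an instrumented execution counter reproduces the
accountant on a micro configuration (tested).

## Objectives

Focal loss `−(1/I) Σᵢ Σⱼ α(1−P_ij)^γ Y_ij log P_ij` with defaults
`α = 0.25, γ = 2` (standard for this loss family; both exposed).  Dice loss
`1 − 2ΣPY/(ΣP²+ΣY²)` accumulates over **all voxels and classes in one
fraction** — the printed form of this loss sums both indices through a
single quotient — with smoothing constant 10⁻⁵ guarding empty targets.  The
hybrid is `λ₁·dice + λ₂·focal` with `λ₁ = λ₂ = 1` (a plain sum) by
default.  Targets are one-hot over the four dense classes, optionally
label-smoothed (ε = 0.1 in training); with smoothing, the focal/CE minimum
sits at the smoothed target itself (tested by grid search).

## Metrics

All seven metrics operate on binary region masks derived from the
`{0,1,2,4}` label convention: ET = {4}, TC = {1,4}, WT = {1,2,4} (nested by
construction).  Conventions the formulas leave open:

* **Boundary**: a mask voxel with ≥ 1 background voxel in its
  6-neighborhood; volume borders count as background.
* **Distances**: Euclidean, in mm via the voxel spacing, computed with a
  distance transform and verified against an O(n²) pairwise oracle.
* **Empty masks**: DSC and NSD are 1 when both masks are empty, NSD is 0
  when exactly one is; HD95/MASD return NaN with a warning; zero-denominator
  rates return 0 with a warning.
* **NSD tolerance**: τ = 1 mm by default, configurable.

## Optimization recipe

Adam, initial learning rate 10⁻³, weight decay 10⁻⁵ (classic L2 in the
gradient), batch size 2, 140 epochs; reduce-on-plateau halves the rate
after 5 epochs without validation-DSC improvement; early stopping after 15
non-improving epochs (the plateau patience is published, the early-stopping
patience is this package's choice); gradient clipping to unit global norm
(value unpublished; 1.0 chosen, configurable); dropout 0.2 on MLP and
projection paths, disabled in inference; label smoothing 0.1.  Runs are
deterministic for a fixed seed: model initialization, dropout streams and
batch order all derive from explicit generators.

The numerics are float64 numpy throughout, with max-subtracted softmax and
log probabilities clamped at 10⁻¹².  Reverse-mode differentiation is
provided by the package's own tape engine (`vitunet3d.autograd`), verified
against central finite differences for every operation class.

## Synthetic phantoms

`generate_phantom` emulates the *layout* of a multimodal tumor case: four
co-registered modalities, labels `{0,1,2,4}` arranged as a necrotic core
inside an enhancing shell inside an edema halo (nested ellipsoids with mild
anisotropy), qualitative modality contrasts (enhancing rim brightest on
T1ce, edema brightest on T2/FLAIR) and additive Gaussian noise (σ = 0.1 on
unit-scale intensities).  Defaults: 64³ grid, 5 % tumor volume fraction,
shell/core at 0.65/0.40 of the outer radii, 1 mm isotropic spacing.

Phantoms deliberately do **not** emulate: brain anatomy or a skull-stripped
foreground, bias fields, irregular or multifocal tumor shapes, partial-
volume effects, anisotropic BraTS spacing, or inter-scanner intensity
variation.  Tests passing on phantoms therefore establish that the
pipeline, gradients, optimization and metrics are correct — not that the
reported clinical accuracy transfers; reproducing published accuracy tables
requires the real accession and GPU-scale training, which is out of scope
here.

## Desk-scale problem sizes

The test suite and the reproduction script run the full-size configuration
only through the analytic accountant and a single instantiation; forward
and training exercises use reduced configurations — `ModelConfig.tiny()`
(embed dim 16, depths `[2,2,2,2]`, decoder `[1,2,2]`, heads `[1,2,4,8]`,
no dropout) on 16³–32³ phantoms — which one CPU core handles in seconds to
a few minutes.
The overfitting probe (one 32³ phantom, 200 Adam steps) reaches foreground
DSC > 0.9 in well under 200 steps at the fixed test seed.

## Known limitations

* Attention materializes full `N×N` score matrices per window; fine for
  window sizes up to a few hundred tokens, not tuned for larger.
* No sliding-window inference for volumes exceeding memory; inputs are
  processed whole (padded as needed).
* No pretrained weights, deep supervision, or test-time augmentation.
* The published architecture leaves decoder depths, dilation factors
  (default `r = 2`, clamped per stage) and the position-encoding resize
  target unstated; the choices above are recorded here and in the config
  surface rather than hidden.
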