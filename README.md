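# vitunet3d

Volumetric brain-tumor segmentation with a pure 3D vision-transformer
U-Net: alternating **window** and **dilated-window** multi-head
self-attention in a hierarchical encoder–decoder, a **dynamic
input-dependent position encoding**, a hybrid **dice + focal** training
objective, and the standard **seven-metric** evaluation suite over the
BraTS tumor regions (whole tumor, tumor core, enhancing tumor).

The package is aimed at researchers who want a transparent, CPU-runnable
reference implementation of this architecture family: every component —
including the reverse-mode autodiff the model trains with — is plain
numpy/scipy, and an analytic accountant reproduces the parameter and FLOP
budget of the full-size configuration without ever materializing a
128³ forward pass.

## The model

An input volume `X ∈ R^(3×D×H×W)` (T1ce, T2, FLAIR channels) is embedded
into tokens by a linear projection of non-overlapping `(2×4×4)` patches.
Three encoder stages at channel widths `C, 2C, 4C` (default `C = 96`) each
apply alternating attention pairs and end in a `2×2×2` patch merge; a
bottleneck at `8C` applies two more pairs; a symmetric decoder patch-expands
back up with skip fusion, ending in a per-voxel 4-class linear head.

Each attention pair is

```
x̂ˡ   = 3D-W-MSA(LN(xˡ⁻¹)) + xˡ⁻¹        (local: window attention)
xˡ    = MLP(LN(x̂ˡ)) + x̂ˡ
x̂ˡ⁺¹ = 3D-DW-MSA(LN(xˡ)) + xˡ           (global: dilated-window attention)
xˡ⁺¹ = MLP(LN(x̂ˡ⁺¹)) + x̂ˡ⁺¹
```

with `Attention(Q,K,V) = softmax(QKᵀ/√d + B_rel) V` inside each window and
a depthwise-convolution position encoding (`x_pos = DWConv(x) + x`) ahead
of every pair.  A dilated window gathers every *r*-th token per axis of an
`M = r·p` span, so attention reaches *r*× farther at unchanged cost: the
windowed complexity is `4ΩC² + 2NΩC` multiply-accumulates versus
`4ΩC² + 2Ω²C` for dense attention over `Ω` tokens.

Training minimizes `L = L_dice + L_focal` with
`L_focal = −(1/I) Σᵢ Σⱼ α (1−P_ij)^γ Y_ij log P_ij` and
`L_dice = 1 − 2ΣPY / (ΣP² + ΣY²)`, on label-smoothed targets (ε = 0.1),
with Adam (lr 10⁻³, weight decay 10⁻⁵), gradient clipping, a
reduce-on-plateau schedule and DSC-based early stopping.

Evaluation: DSC, HD95, sensitivity, specificity, precision, NSD and MASD
per region, with distances in millimetres from the voxel spacing.

## Worked example

`python examples/overfit_tiny_phantom.py` fits a reduced configuration
(embed dim 16) to a single synthetic 32³ tumor phantom and prints:

```
step  20  hybrid loss 0.4113  foreground DSC 0.7406
step  40  hybrid loss 0.1794  foreground DSC 0.7962
step  60  hybrid loss 0.0988  foreground DSC 0.8252
step  80  hybrid loss 0.0825  foreground DSC 0.9090
step 100  hybrid loss 0.0777  foreground DSC 0.9515
step 120  hybrid loss 0.0751  foreground DSC 0.9759
```

The hybrid loss falls toward the floor set by label smoothing while the
foreground Dice overlap between the predicted and true tumor masks climbs
past 0.97 — the network memorizes the phantom, demonstrating that gradients
flow end to end through embedding, both attention flavors, merging,
expansion and skip fusion.

`python examples/describe_architecture.py` prints the cost report of the
full-size configuration:

```
parameters (analytic):        50.33 M
parameters (instantiated):    50.33 M
FLOPs per 128^3 volume:      114.01 G
FLOPs per 2D slice:           0.891 G
```

Other examples: `simulate_and_split.py` (phantom suite, 1 % tumor filter,
75/25 and 4-fold splits), `score_segmentation.py` (seven-metric table for a
perturbed mask), `attention_complexity.py` (dense vs windowed attention
cost per stage).

## Command line

The same workflows are exposed as a thin CLI:

```bash
vitunet3d describe --extents 128,128,128
vitunet3d simulate --out suite/ --cases 8 --extents 64,64,64 --seed 0
vitunet3d split    --data suite/ --manifest manifest.csv
vitunet3d train    --data suite/ --manifest manifest.csv --out run/ \
                   --model-config model.yaml --train-config train.yaml
vitunet3d evaluate --checkpoint run/ --data suite/ --manifest manifest.csv --out eval.csv
vitunet3d predict  --checkpoint run/ --data suite/ --case-id phantom0000 --out pred.nii
vitunet3d score    --prediction pred.nii --reference suite/phantom0000_seg.nii
```

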