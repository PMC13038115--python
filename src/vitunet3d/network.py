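"""U-shaped 3D transformer segmentation network and its cost accountant.

Architecture: a patch-embedding layer turns the multimodal volume into a
token grid at 1/(2,4,4) resolution; three encoder stages of alternating
window / dilated-window attention each end in a patch-merging layer that
halves every spatial extent and doubles the channel width; a bottleneck of
two alternating pairs operates at the coarsest grid; a symmetric decoder
patch-expands back up, fusing each level with the matching encoder features
through a linear reduction, and a final expansion restores the input
resolution before a per-voxel linear classifier.

:func:`count_parameters` and :func:`count_flops` are analytic accountants
that walk the same configuration the model is built from, so their numbers
can be cross-checked against an instantiated network parameter-for-parameter.
The FLOP convention counts one multiply-accumulate as one FLOP over all
linear/convolution layers plus the attention score and value matmuls;
normalization, softmax and activations are excluded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .attention import (DilationSpec, TransformerPairBlock, WindowSpec,
                        complexity_estimate)
from .autograd import Tensor, concat, no_grad
from .nn import LayerNorm, Linear, Module

__all__ = [
    "ModelConfig",
    "CostReport",
    "VitUNet3D",
    "count_parameters",
    "count_flops",
    "describe",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architectural hyperparameters.

    ``depths`` are attention sub-block counts for the three encoder stages
    plus the bottleneck (each window/dilated pair is two sub-blocks; the
    bottleneck's two pair-blocks hold four attention layers).
    ``decoder_depths`` run coarse-to-fine over the three decoder stages.
    ``window`` is (D, H, W) tokens per window; the published (8, 8, 2) size
    is oriented with the short axis along depth, matching the asymmetric
    (2, 4, 4) patch.  Windows and dilations are clamped per stage against
    the token grid of ``ref_extents``, which fixes the parameter count
    independently of the runtime input size.
    """

    in_channels: int = 3
    num_classes: int = 4
    embed_dim: int = 96
    patch_size: tuple[int, int, int] = (2, 4, 4)
    depths: tuple[int, ...] = (2, 2, 6, 4)
    decoder_depths: tuple[int, int, int] = (1, 2, 4)
    heads: tuple[int, int, int, int] = (3, 6, 12, 24)
    window: tuple[int, int, int] = (2, 8, 8)
    dilation: tuple[int, int, int] = (2, 2, 2)
    mlp_ratio: float = 4.0
    qkv_bias: bool = True
    dropout: float = 0.2
    attn_dropout: float = 0.0
    pad_policy: str = "pad"
    ref_extents: tuple[int, int, int] = (128, 128, 128)

    def __post_init__(self):
        for s, h in enumerate(self.heads):
            if (self.embed_dim * 2 ** s) % h:
                raise ValueError(
                    f"heads[{s}]={h} does not divide stage channels "
                    f"{self.embed_dim * 2 ** s}")
        if len(self.depths) != 4 or len(self.decoder_depths) != 3:
            raise ValueError("depths must have 4 entries, decoder_depths 3")

    @classmethod
    def tiny(cls, extents=(32, 32, 32)) -> "ModelConfig":
        """Reduced configuration for desk-scale experiments and tests."""
        return cls(embed_dim=16, depths=(2, 2, 2, 2), decoder_depths=(1, 2, 2),
                   heads=(1, 2, 4, 8), dropout=0.0, ref_extents=tuple(extents))

    # -- geometry -------------------------------------------------------------
    def stage_channels(self) -> list[int]:
        return [self.embed_dim * 2 ** s for s in range(4)]

    def embed_grid(self, extents) -> tuple[int, int, int]:
        """Token grid after patch embedding, padding to full coverage."""
        return tuple(-(-e // p) for e, p in zip(extents, self.patch_size))

    def stage_extents(self, extents) -> list[tuple[int, int, int]]:
        grid = self.embed_grid(extents)
        out = []
        for s in range(4):
            out.append(grid)
            if s < 3:
                grid = tuple(-(-g // 2) for g in grid)
        return out

    def stage_windows(self) -> list[WindowSpec]:
        exts = self.stage_extents(self.ref_extents)
        return [WindowSpec(*self.window).clamped(e) for e in exts]

    def stage_dilations(self) -> list[DilationSpec]:
        exts = self.stage_extents(self.ref_extents)
        return [DilationSpec(*self.dilation).clamped(w, e)
                for w, e in zip(self.stage_windows(), exts)]

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for k in ("patch_size", "depths", "decoder_depths", "heads", "window",
                  "dilation", "ref_extents"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class CostReport:
    """Learnable-scalar and multiply-accumulate budget of a configuration."""

    parameter_count: int
    flop_count: int
    input_extents: tuple[int, int, int]
    convention: str = "1 FLOP = 1 multiply-accumulate; norm/softmax excluded"

    @property
    def params_m(self) -> float:
        return self.parameter_count / 1e6

    @property
    def flops_g(self) -> float:
        return self.flop_count / 1e9

    @property
    def per_slice_flops(self) -> float:
        return self.flop_count / self.input_extents[0]

    @property
    def per_slice_g(self) -> float:
        return self.per_slice_flops / 1e9

    def to_json(self) -> str:
        return json.dumps({
            "parameters": self.parameter_count,
            "parameters_millions": round(self.params_m, 4),
            "flops": self.flop_count,
            "flops_giga": round(self.flops_g, 4),
            "flops_per_slice_giga": round(self.per_slice_g, 4),
            "input_extents": list(self.input_extents),
            "convention": self.convention,
        }, indent=2)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class PatchEmbed(Module):
    """Linear projection of non-overlapping (2,4,4) patches to tokens."""

    def __init__(self, in_channels: int, dim: int, patch: tuple[int, int, int],
                 rng, pad_policy: str = "pad"):
        super().__init__()
        self.patch = patch
        self.in_channels = in_channels
        self.pad_policy = pad_policy
        self.proj = Linear(in_channels * int(np.prod(patch)), dim, rng=rng)
        self.norm = LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        """(B, C_in, D, H, W) -> (B, D', H', W', dim)."""
        b, c, d, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        pd, ph, pw = self.patch
        pads = [(-e) % p for e, p in zip((d, h, w), self.patch)]
        if any(pads):
            if self.pad_policy == "strict":
                raise ValueError(f"extents {(d, h, w)} not divisible by patch {self.patch}")
            x = x.pad(((0, 0), (0, 0), (0, pads[0]), (0, pads[1]), (0, pads[2])))
        b, c, d, h, w = x.shape
        x = x.reshape(b, c, d // pd, pd, h // ph, ph, w // pw, pw)
        x = x.transpose(0, 2, 4, 6, 1, 3, 5, 7)
        x = x.reshape(b, d // pd, h // ph, w // pw, c * pd * ph * pw)
        return self.norm(self.proj(x))


class PatchMerge(Module):
    """2x2x2 token fusion: concat 8 neighbors (8C) -> linear to 2C."""

    def __init__(self, dim: int, rng, pad_policy: str = "pad"):
        super().__init__()
        self.pad_policy = pad_policy
        self.norm = LayerNorm(8 * dim)
        self.reduce = Linear(8 * dim, 2 * dim, bias=False, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        b, d, h, w, c = x.shape
        pads = [e % 2 for e in (d, h, w)]
        if any(pads):
            if self.pad_policy == "strict":
                raise ValueError(f"odd extents {(d, h, w)} under strict merging")
            x = x.pad(((0, 0), (0, pads[0]), (0, pads[1]), (0, pads[2]), (0, 0)))
        b, d, h, w, c = x.shape
        x = x.reshape(b, d // 2, 2, h // 2, 2, w // 2, 2, c)
        x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)
        x = x.reshape(b, d // 2, h // 2, w // 2, 8 * c)
        return self.reduce(self.norm(x))


class PatchExpand(Module):
    """2x2x2 token expansion: linear C -> 8 * C/2, redistributed spatially."""

    def __init__(self, dim: int, rng):
        super().__init__()
        if dim % 2:
            raise ValueError(f"channel count must be even to expand: {dim}")
        self.dim_out = dim // 2
        self.expand = Linear(dim, 4 * dim, bias=False, rng=rng)
        self.norm = LayerNorm(self.dim_out)

    def forward(self, x: Tensor) -> Tensor:
        b, d, h, w, c = x.shape
        x = self.expand(x)
        x = x.reshape(b, d, h, w, 2, 2, 2, self.dim_out)
        x = x.transpose(0, 1, 4, 2, 5, 3, 6, 7)
        x = x.reshape(b, 2 * d, 2 * h, 2 * w, self.dim_out)
        return self.norm(x)


class FinalExpand(Module):
    """Expansion by the full patch size back to voxel resolution."""

    def __init__(self, dim: int, patch: tuple[int, int, int], rng):
        super().__init__()
        self.patch = patch
        self.dim = dim
        self.expand = Linear(dim, int(np.prod(patch)) * dim, bias=False, rng=rng)
        self.norm = LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        b, d, h, w, c = x.shape
        pd, ph, pw = self.patch
        x = self.expand(x)
        x = x.reshape(b, d, h, w, pd, ph, pw, self.dim)
        x = x.transpose(0, 1, 4, 2, 5, 3, 6, 7)
        x = x.reshape(b, d * pd, h * ph, w * pw, self.dim)
        return self.norm(x)


class SkipFuse(Module):
    """Concatenate decoder and encoder features; reduce back to C."""

    def __init__(self, dim: int, rng):
        super().__init__()
        self.reduce = Linear(2 * dim, dim, rng=rng)

    def forward(self, dec: Tensor, enc: Tensor) -> Tensor:
        if dec.shape[:4] != enc.shape[:4]:
            raise ValueError(
                f"skip fusion spatial mismatch: {dec.shape} vs {enc.shape}")
        return self.reduce(concat([dec, enc], axis=-1))


def _crop_spatial(x: Tensor, target: tuple[int, int, int]) -> Tensor:
    b, d, h, w, c = x.shape
    td, th, tw = target
    if (d, h, w) == (td, th, tw):
        return x
    return x[:, :td, :th, :tw, :]


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class VitUNet3D(Module):
    """End-to-end volumetric segmentation transformer.

    ``forward`` maps ``(B, in_channels, D, H, W)`` to per-class scores
    ``(B, num_classes, D, H, W)``; spatial extents are preserved (padding is
    applied and cropped internally when extents are not multiples of the
    x32 reduction).
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        chans = cfg.stage_channels()
        wins = cfg.stage_windows()
        dils = cfg.stage_dilations()
        pp = cfg.pad_policy

        self.patch_embed = PatchEmbed(cfg.in_channels, cfg.embed_dim,
                                      cfg.patch_size, rng, pp)
        enc = []
        merges = []
        for s in range(3):
            enc.append(TransformerPairBlock(
                chans[s], cfg.depths[s], cfg.heads[s], wins[s], dils[s],
                cfg.mlp_ratio, cfg.dropout, cfg.attn_dropout, cfg.qkv_bias,
                rng, pp))
            merges.append(PatchMerge(chans[s], rng, pp))
        self.encoder = enc
        self.merges = merges
        self.bottleneck = TransformerPairBlock(
            chans[3], cfg.depths[3], cfg.heads[3], wins[3], dils[3],
            cfg.mlp_ratio, cfg.dropout, cfg.attn_dropout, cfg.qkv_bias, rng, pp)

        expands = []
        fuses = []
        dec = []
        for i, s in enumerate((2, 1, 0)):
            expands.append(PatchExpand(chans[s + 1], rng))
            fuses.append(SkipFuse(chans[s], rng))
            dec.append(TransformerPairBlock(
                chans[s], cfg.decoder_depths[i], cfg.heads[s], wins[s], dils[s],
                cfg.mlp_ratio, cfg.dropout, cfg.attn_dropout, cfg.qkv_bias,
                rng, pp))
        self.expands = expands
        self.fuses = fuses
        self.decoder = dec
        self.final_expand = FinalExpand(cfg.embed_dim, cfg.patch_size, rng)
        self.head = Linear(cfg.embed_dim, cfg.num_classes, rng=rng)

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim != 5:
            raise ValueError(f"expected (B, C, D, H, W), got {x.shape}")
        extents = x.shape[2:]
        tokens = self.patch_embed(x)
        skips = []
        for blocks, merge in zip(self.encoder, self.merges):
            tokens = blocks(tokens)
            skips.append(tokens)
            tokens = merge(tokens)
        tokens = self.bottleneck(tokens)
        for expand, fuse, blocks, skip in zip(
                self.expands, self.fuses, self.decoder, reversed(skips)):
            tokens = expand(tokens)
            tokens = _crop_spatial(tokens, skip.shape[1:4])
            tokens = fuse(tokens, skip)
            tokens = blocks(tokens)
        voxels = self.final_expand(tokens)
        voxels = _crop_spatial(voxels, extents)
        scores = self.head(voxels)
        return scores.transpose(0, 4, 1, 2, 3)

    def predict_labels(self, x) -> np.ndarray:
        """Argmax class decoding in inference mode: (B, D, H, W) ints."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                scores = self.forward(x)
        finally:
            self.train(was_training)
        return np.argmax(scores.data, axis=1)


# ---------------------------------------------------------------------------
# accountant
# ---------------------------------------------------------------------------

def _subblock_params(c: int, heads: int, win: WindowSpec, mlp_ratio: float,
                     qkv_bias: bool) -> int:
    pd, ph, pw = win.shape
    table = (2 * pd - 1) * (2 * ph - 1) * (2 * pw - 1) * heads
    hidden = int(c * mlp_ratio)
    n = 2 * c                                  # norm1
    n += 3 * c * c + (3 * c if qkv_bias else 0)  # qkv
    n += c * c + c                             # proj
    n += table
    n += 2 * c                                 # norm2
    n += c * hidden + hidden + hidden * c + c  # mlp
    return n


def count_parameters(cfg: ModelConfig) -> CostReport:
    """Analytic learnable-scalar count; independent of the input size.

    Enumerates the same layer inventory the model constructor builds, so
    the total matches ``VitUNet3D(cfg).num_parameters()`` exactly.
    """
    chans = cfg.stage_channels()
    wins = cfg.stage_windows()
    patch_vol = int(np.prod(cfg.patch_size))
    p = cfg.in_channels * patch_vol * cfg.embed_dim + cfg.embed_dim  # embed proj
    p += 2 * cfg.embed_dim                                           # embed norm
    for s in range(4):
        c = chans[s]
        depth = cfg.depths[s]
        p += depth * _subblock_params(c, cfg.heads[s], wins[s], cfg.mlp_ratio,
                                      cfg.qkv_bias)
        p += ((depth + 1) // 2) * 28 * c  # position encoding per pair
        if s < 3:
            p += 16 * c * c + 16 * c      # merge: linear 8C->2C + norm(8C)
    for i, s in enumerate((2, 1, 0)):
        c = chans[s]
        p += chans[s + 1] * 4 * chans[s + 1] + 2 * c  # expand + norm(C)
        p += 2 * c * c + c                            # skip fusion
        depth = cfg.decoder_depths[i]
        p += depth * _subblock_params(c, cfg.heads[s], wins[s], cfg.mlp_ratio,
                                      cfg.qkv_bias)
        p += ((depth + 1) // 2) * 28 * c
    p += cfg.embed_dim * patch_vol * cfg.embed_dim + 2 * cfg.embed_dim  # final
    p += cfg.embed_dim * cfg.num_classes + cfg.num_classes              # head
    return CostReport(parameter_count=p, flop_count=0,
                      input_extents=cfg.ref_extents)


def count_flops(cfg: ModelConfig, extents: tuple[int, int, int] | None = None
                ) -> CostReport:
    """Analytic multiply-accumulate count of one forward pass.

    Attention layers are charged via :func:`complexity_estimate` on the
    window-padded token count of their stage; linear and depthwise-conv
    layers are charged in_features x out_features per output element.
    """
    extents = tuple(extents or cfg.ref_extents)
    chans = cfg.stage_channels()
    wins = cfg.stage_windows()
    stage_exts = cfg.stage_extents(extents)
    patch_vol = int(np.prod(cfg.patch_size))

    def tokens(ext):
        return int(np.prod(ext))

    def padded_tokens(ext, win: WindowSpec, dil: DilationSpec | None):
        mult = win.shape if dil is None else dil.span(win)
        return int(np.prod([-(-e // m) * m for e, m in zip(ext, mult)]))

    dils = cfg.stage_dilations()
    f = tokens(stage_exts[0]) * cfg.in_channels * patch_vol * cfg.embed_dim

    def stage_flops(s: int, depth: int) -> int:
        c = chans[s]
        t = tokens(stage_exts[s])
        hidden = int(c * cfg.mlp_ratio)
        total = 0
        for i in range(depth):
            dil = dils[s] if i % 2 == 1 else None
            t_pad = padded_tokens(stage_exts[s], wins[s], dil)
            total += complexity_estimate(t_pad, c, wins[s].n_tokens, "windowed")
            total += t * 2 * c * hidden                      # mlp
        total += ((depth + 1) // 2) * t * c * 27             # position encoding
        return total

    for s in range(4):
        f += stage_flops(s, cfg.depths[s])
        if s < 3:
            c = chans[s]
            f += tokens(stage_exts[s + 1]) * 16 * c * c      # merge
    for i, s in enumerate((2, 1, 0)):
        c_in = chans[s + 1]
        f += tokens(stage_exts[s + 1]) * 4 * c_in * c_in     # expand
        f += tokens(stage_exts[s]) * 2 * chans[s] * chans[s]  # skip fusion
        f += stage_flops(s, cfg.decoder_depths[i])
    f += tokens(stage_exts[0]) * cfg.embed_dim * patch_vol * cfg.embed_dim
    f += int(np.prod(extents)) * cfg.embed_dim * cfg.num_classes
    params = count_parameters(cfg).parameter_count
    return CostReport(parameter_count=params, flop_count=f,
                      input_extents=extents)


def describe(cfg: ModelConfig, extents: tuple[int, int, int] | None = None
             ) -> CostReport:
    """Full cost report (parameters + FLOPs) for a configuration."""
    return count_flops(cfg, extents)
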