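"""Windowed and dilated-window 3D self-attention.

The building blocks of the segmentation transformer:

* :func:`dipe_encode` / :class:`DIPE` — dynamic input-dependent position
  encoding: a per-channel (depthwise) 3x3x3 convolution of the feature map
  added back residually, so positional information is derived from the input
  itself instead of a fixed table.
* :func:`partition_windows` / :func:`partition_dilated_windows` — tiling of a
  token grid into non-overlapping windows.  The dilated variant groups every
  r-th token (per axis) of an ``M = r * p`` block into one window, so each
  window keeps the same token count ``N`` while its receptive field grows by
  the dilation factor; the r^3 residue classes of each block tile the grid
  exactly once.
* :class:`WindowAttention` — multi-head self-attention inside each window
  with a learned relative position bias ``B_rel`` indexed by the offset
  between token positions (window-local coordinates, also for dilated
  windows).
* :class:`TransformerPairBlock` — the alternating unit: position encoding,
  then a window-attention sub-block and a dilated-window sub-block, each
  pre-norm with an MLP and residual connections.
* :func:`complexity_estimate` — analytic multiply-accumulate counts of dense
  vs. windowed attention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, no_grad
from .nn import Dropout, LayerNorm, Linear, Module, Parameter, trunc_normal

__all__ = [
    "WindowSpec",
    "DilationSpec",
    "AttentionConfig",
    "dipe_encode",
    "partition_windows",
    "partition_dilated_windows",
    "reverse_windows",
    "window_attention",
    "complexity_estimate",
    "DIPE",
    "WindowAttention",
    "Mlp",
    "TransformerPairBlock",
]


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowSpec:
    """Tokens per window along (D, H, W)."""

    p_d: int
    p_h: int
    p_w: int

    def __post_init__(self):
        if min(self.p_d, self.p_h, self.p_w) < 1:
            raise ValueError(f"window extents must be positive: {self}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.p_d, self.p_h, self.p_w)

    @property
    def n_tokens(self) -> int:
        return self.p_d * self.p_h * self.p_w

    def clamped(self, extents: tuple[int, int, int]) -> "WindowSpec":
        return WindowSpec(*(min(p, e) for p, e in zip(self.shape, extents)))


@dataclass(frozen=True)
class DilationSpec:
    """Per-axis dilation factors; window span is ``M = r * p`` per axis."""

    r_d: int
    r_h: int
    r_w: int

    def __post_init__(self):
        if min(self.r_d, self.r_h, self.r_w) < 1:
            raise ValueError(f"dilation factors must be positive: {self}")

    @property
    def factors(self) -> tuple[int, int, int]:
        return (self.r_d, self.r_h, self.r_w)

    def span(self, window: WindowSpec) -> tuple[int, int, int]:
        return tuple(r * p for r, p in zip(self.factors, window.shape))

    def clamped(self, window: WindowSpec, extents: tuple[int, int, int]) -> "DilationSpec":
        """Largest r' <= r per axis with r' * p <= extent."""
        out = []
        for r, p, e in zip(self.factors, window.shape, extents):
            out.append(max(1, min(r, e // p)))
        return DilationSpec(*out)


@dataclass(frozen=True)
class AttentionConfig:
    num_heads: int
    head_dim: int
    qkv_bias: bool = True
    attn_dropout: float = 0.0
    proj_dropout: float = 0.0

    @property
    def dim(self) -> int:
        return self.num_heads * self.head_dim


# ---------------------------------------------------------------------------
# position encoding
# ---------------------------------------------------------------------------

def _depthwise_conv3d(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """3x3x3 depthwise convolution, stride 1, zero padding.

    ``x`` is channels-last ``(B, D, H, W, C)``; ``weight`` is ``(27, C)``
    (one 3x3x3 filter per channel); computed as a sum of 27 shifted copies.
    """
    b, d, h, w, c = x.shape
    xp = x.pad(((0, 0), (1, 1), (1, 1), (1, 1), (0, 0)))
    out = None
    k = 0
    for dz in range(3):
        for dy in range(3):
            for dx in range(3):
                term = xp[:, dz:dz + d, dy:dy + h, dx:dx + w, :] * weight[k]
                out = term if out is None else out + term
                k += 1
    if bias is not None:
        out = out + bias
    return out


class DIPE(Module):
    """Dynamic input-dependent position encoding.

    ``x_pos = resize_back(DWConv(resize(x))) + x``.  The resize pair is an
    identity by default (the convolution runs at native resolution); the
    hooks are kept so a coarser encoding grid can be configured.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None,
                 resize=None, resize_back=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.weight = Parameter(trunc_normal(rng, (27, channels)))
        self.bias = Parameter(np.zeros(channels))
        self.resize = resize or (lambda t: t)
        self.resize_back = resize_back or (lambda t: t)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[-1] != self.channels:
            raise ValueError(
                f"DIPE built for {self.channels} channels, got {x.shape[-1]}")
        inner = _depthwise_conv3d(self.resize(x), self.weight, self.bias)
        return self.resize_back(inner) + x


def dipe_encode(x, kernel: np.ndarray, bias: np.ndarray | None = None):
    """Functional position encoding on a ``(B, C, D, H, W)`` array.

    ``kernel`` has shape ``(C, 3, 3, 3)`` — one filter per channel.  Returns
    an array of the same shape: depthwise convolution plus residual input.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 5:
        raise ValueError(f"expected (B, C, D, H, W), got shape {x.shape}")
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.shape != (x.shape[1], 3, 3, 3):
        raise ValueError(
            f"kernel shape {kernel.shape} does not match {x.shape[1]} channels")
    xt = Tensor(np.moveaxis(x, 1, -1))
    w = Tensor(kernel.reshape(kernel.shape[0], 27).T)
    b = Tensor(np.asarray(bias, dtype=np.float64)) if bias is not None else None
    with no_grad():
        out = _depthwise_conv3d(xt, w, b) + xt
    return np.moveaxis(out.data, -1, 1)


# ---------------------------------------------------------------------------
# window partitioning
# ---------------------------------------------------------------------------

def _pad_to_multiple(x: Tensor, multiples: tuple[int, int, int], policy: str):
    """Pad the (D, H, W) axes of channels-last tokens up to multiples."""
    b, d, h, w, c = x.shape
    pads = [(-e) % m for e, m in zip((d, h, w), multiples)]
    if any(pads):
        if policy == "strict":
            raise ValueError(
                f"extents {(d, h, w)} not divisible by {multiples} under strict padding")
        x = x.pad(((0, 0), (0, pads[0]), (0, pads[1]), (0, pads[2]), (0, 0)))
    return x, (d, h, w)


def partition_windows(x, spec: WindowSpec, policy: str = "pad"):
    """Tile a channels-last token grid into non-overlapping windows.

    Parameters
    ----------
    x : Tensor or ndarray, shape (B, D, H, W, C)
    spec : WindowSpec

    Returns
    -------
    windows : Tensor, shape (B * n_windows, N, C)
    index_map : ndarray of int, shape (B * n_windows, N)
        Flat (d*H*W + h*W + w) grid index of every token slot; -1 marks
        padding slots.  Sufficient to invert the partition.
    """
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x, dtype=np.float64))
    x, orig = _pad_to_multiple(x, spec.shape, policy)
    b, d, h, w, c = x.shape
    pd, ph, pw = spec.shape
    nd, nh, nw = d // pd, h // ph, w // pw
    xw = x.reshape(b, nd, pd, nh, ph, nw, pw, c)
    xw = xw.transpose(0, 1, 3, 5, 2, 4, 6, 7)
    windows = xw.reshape(b * nd * nh * nw, spec.n_tokens, c)
    index_map = _window_index_map(orig, (d, h, w), spec.shape, None, b)
    return windows, index_map


def partition_dilated_windows(x, spec: WindowSpec, dil: DilationSpec,
                              policy: str = "pad"):
    """Dilated-window tiling: every r-th token of each M-span block.

    Each window spans a contiguous ``M_D x M_H x M_W`` block but contains
    only the ``p_D * p_H * p_W`` tokens on the stride-``r`` lattice of one
    residue class; the union of residue classes covers every token exactly
    once.  With ``r = (1, 1, 1)`` this reduces to :func:`partition_windows`.
    Returns the same ``(windows, index_map)`` pair.
    """
    if not isinstance(x, Tensor):
        x = Tensor(np.asarray(x, dtype=np.float64))
    span = dil.span(spec)
    x, orig = _pad_to_multiple(x, span, policy)
    b, d, h, w, c = x.shape
    pd, ph, pw = spec.shape
    rd, rh, rw = dil.factors
    nd, nh, nw = d // (pd * rd), h // (ph * rh), w // (pw * rw)
    xw = x.reshape(b, nd, pd, rd, nh, ph, rh, nw, pw, rw, c)
    xw = xw.transpose(0, 1, 3, 4, 6, 7, 9, 2, 5, 8, 10)
    windows = xw.reshape(b * nd * rd * nh * rh * nw * rw, spec.n_tokens, c)
    index_map = _window_index_map(orig, (d, h, w), spec.shape, dil.factors, b)
    return windows, index_map


def _window_index_map(orig, padded, window, factors, batch) -> np.ndarray:
    """Flat grid index per window slot (-1 for padding), replicated per batch."""
    d, h, w = padded
    od, oh, ow = orig
    flat = np.full((d, h, w), -1, dtype=np.int64)
    flat[:od, :oh, :ow] = np.arange(od * oh * ow).reshape(od, oh, ow)
    pd, ph, pw = window
    if factors is None:
        nd, nh, nw = d // pd, h // ph, w // pw
        fm = flat.reshape(nd, pd, nh, ph, nw, pw).transpose(0, 2, 4, 1, 3, 5)
    else:
        rd, rh, rw = factors
        nd, nh, nw = d // (pd * rd), h // (ph * rh), w // (pw * rw)
        fm = flat.reshape(nd, pd, rd, nh, ph, rh, nw, pw, rw)
        fm = fm.transpose(0, 2, 3, 5, 6, 8, 1, 4, 7)
    per_item = fm.reshape(-1, pd * ph * pw)
    return np.tile(per_item, (batch, 1))


def reverse_windows(windows, index_map: np.ndarray, grid: tuple[int, int, int],
                    batch: int):
    """Invert a (possibly dilated, possibly padded) window partition.

    ``grid`` is the unpadded (D, H, W); returns ``(B, D, H, W, C)``.
    """
    if not isinstance(windows, Tensor):
        windows = Tensor(np.asarray(windows, dtype=np.float64))
    nw_total, n, c = windows.shape
    per_item = nw_total // batch
    d, h, w = grid
    flat = windows.reshape(batch, per_item * n, c)
    idx = index_map[:per_item].reshape(-1)
    keep = idx >= 0
    order = np.argsort(idx[keep])
    sel = np.where(keep)[0][order]
    out = flat[:, sel, :]
    return out.reshape(batch, d, h, w, c)


def window_key_mask(index_map: np.ndarray) -> np.ndarray | None:
    """Additive attention mask excluding padded key slots, or None."""
    if (index_map >= 0).all():
        return None
    neg = np.where(index_map < 0, -1e9, 0.0)
    return neg[:, None, None, :]  # (nW, 1 head, 1 query, N keys)


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

def _relative_index(window: WindowSpec) -> np.ndarray:
    """(N, N) index into a ((2pD-1)(2pH-1)(2pW-1),) offset table."""
    pd, ph, pw = window.shape
    coords = np.stack(np.meshgrid(
        np.arange(pd), np.arange(ph), np.arange(pw), indexing="ij"),
        axis=0).reshape(3, -1)
    rel = coords[:, :, None] - coords[:, None, :]
    rel[0] += pd - 1
    rel[1] += ph - 1
    rel[2] += pw - 1
    return (rel[0] * (2 * ph - 1) * (2 * pw - 1)
            + rel[1] * (2 * pw - 1) + rel[2]).astype(np.int64)


class WindowAttention(Module):
    """Multi-head self-attention within windows, with relative position bias.

    ``softmax(Q K^T / sqrt(d) + B_rel [+ mask]) V`` followed by an output
    projection.  The bias table is shared across all windows of the stage and
    indexed purely by the offset between two token positions.
    """

    def __init__(self, cfg: AttentionConfig, window: WindowSpec,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.window = window
        dim = cfg.dim
        pd, ph, pw = window.shape
        table_len = (2 * pd - 1) * (2 * ph - 1) * (2 * pw - 1)
        self.bias_table = Parameter(trunc_normal(rng, (table_len, cfg.num_heads)))
        self.rel_index = _relative_index(window).reshape(-1)
        self.qkv = Linear(dim, 3 * dim, bias=cfg.qkv_bias, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)
        self.attn_drop = Dropout(cfg.attn_dropout, rng=np.random.default_rng(rng.integers(2**31)))
        self.proj_drop = Dropout(cfg.proj_dropout, rng=np.random.default_rng(rng.integers(2**31)))

    def forward(self, tokens: Tensor, mask: np.ndarray | None = None) -> Tensor:
        nw, n, c = tokens.shape
        heads, d = self.cfg.num_heads, self.cfg.head_dim
        if heads * d != c:
            raise ValueError(f"token dim {c} != num_heads*head_dim {heads * d}")
        if not np.isfinite(tokens.data).all():
            raise FloatingPointError("non-finite values entering window attention")
        qkv = self.qkv(tokens).reshape(nw, n, 3, heads, d).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]
        attn = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        bias = self.bias_table.take0(self.rel_index)  # (N*N, heads)
        bias = bias.reshape(n, n, heads).transpose(2, 0, 1)
        attn = attn + bias
        if mask is not None:
            attn = attn + Tensor(mask)
        attn = attn.softmax(axis=-1)
        attn = self.attn_drop(attn)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(nw, n, c)
        return self.proj_drop(self.proj(out))


def window_attention(tokens, cfg: AttentionConfig, *, qkv_weight, qkv_bias,
                     proj_weight, proj_bias, bias_table, window: WindowSpec,
                     mask=None) -> np.ndarray:
    """Functional windowed attention on a ``(nW, N, C)`` array with explicit
    weights — convenient for oracle tests; inference only."""
    attn = WindowAttention(cfg, window)
    attn.qkv.weight.data = np.asarray(qkv_weight, dtype=np.float64)
    if attn.qkv.bias is not None:
        attn.qkv.bias.data = np.asarray(qkv_bias, dtype=np.float64)
    attn.proj.weight.data = np.asarray(proj_weight, dtype=np.float64)
    attn.proj.bias.data = np.asarray(proj_bias, dtype=np.float64)
    attn.bias_table.data = np.asarray(bias_table, dtype=np.float64)
    attn.eval()
    with no_grad():
        out = attn(Tensor(np.asarray(tokens, dtype=np.float64)), mask=mask)
    return out.data


# ---------------------------------------------------------------------------
# transformer blocks
# ---------------------------------------------------------------------------

class Mlp(Module):
    def __init__(self, dim: int, ratio: float, dropout: float,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        hidden = int(dim * ratio)
        self.fc1 = Linear(dim, hidden, rng=rng)
        self.fc2 = Linear(hidden, dim, rng=rng)
        self.drop1 = Dropout(dropout, rng=np.random.default_rng(rng.integers(2**31)))
        self.drop2 = Dropout(dropout, rng=np.random.default_rng(rng.integers(2**31)))

    def forward(self, x: Tensor) -> Tensor:
        return self.drop2(self.fc2(self.drop1(self.fc1(x).gelu())))


class AttentionSubBlock(Module):
    """Pre-norm attention + MLP sub-block on a (B, D, H, W, C) grid."""

    def __init__(self, dim: int, heads: int, window: WindowSpec,
                 dilation: DilationSpec | None, mlp_ratio: float,
                 dropout: float, attn_dropout: float, qkv_bias: bool,
                 rng: np.random.Generator, pad_policy: str = "pad"):
        super().__init__()
        if dim % heads:
            raise ValueError(f"heads {heads} must divide channels {dim}")
        cfg = AttentionConfig(heads, dim // heads, qkv_bias=qkv_bias,
                              attn_dropout=attn_dropout, proj_dropout=dropout)
        self.window = window
        self.dilation = dilation
        self.pad_policy = pad_policy
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(cfg, window, rng=rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, mlp_ratio, dropout, rng=rng)

    def _attend(self, x: Tensor) -> Tensor:
        b, d, h, w, c = x.shape
        if self.dilation is None:
            win, imap = partition_windows(x, self.window, self.pad_policy)
        else:
            win, imap = partition_dilated_windows(x, self.window, self.dilation,
                                                  self.pad_policy)
        mask = window_key_mask(imap)
        out = self.attn(win, mask=mask)
        return reverse_windows(out, imap, (d, h, w), b)

    def forward(self, x: Tensor) -> Tensor:
        x = self._attend(self.norm1(x)) + x
        return self.mlp(self.norm2(x)) + x


class TransformerPairBlock(Module):
    """Position encoding followed by ``depth`` alternating sub-blocks.

    Even sub-blocks use plain window attention (local), odd ones the dilated
    variant (global); each is pre-norm with an MLP and two residuals.  One
    position-encoding convolution serves each window/dilated pair.
    """

    def __init__(self, dim: int, depth: int, heads: int, window: WindowSpec,
                 dilation: DilationSpec, mlp_ratio: float, dropout: float,
                 attn_dropout: float, qkv_bias: bool,
                 rng: np.random.Generator, pad_policy: str = "pad"):
        super().__init__()
        self.dipes = [DIPE(dim, rng=rng) for _ in range((depth + 1) // 2)]
        blocks = []
        for i in range(depth):
            dil = dilation if i % 2 == 1 else None
            blocks.append(AttentionSubBlock(
                dim, heads, window, dil, mlp_ratio, dropout, attn_dropout,
                qkv_bias, rng, pad_policy))
        self.blocks = blocks

    def forward(self, x: Tensor) -> Tensor:
        for i, blk in enumerate(self.blocks):
            if i % 2 == 0:
                x = self.dipes[i // 2](x)
            x = blk(x)
        return x


# ---------------------------------------------------------------------------
# analytic complexity
# ---------------------------------------------------------------------------

def complexity_estimate(omega: int, channels: int, n_window: int | None = None,
                        mode: str = "windowed") -> int:
    """Multiply-accumulate count of one attention layer on ``omega`` tokens.

    ``dense``:    4 * omega * C^2 + 2 * omega^2 * C
    ``windowed``: 4 * omega * C^2 + 2 * N * omega * C

    The first term covers the Q/K/V and output projections, the second the
    score and value matmuls.  Normalization, softmax and bias adds are
    excluded from the convention.
    """
    if omega < 1 or channels < 1:
        raise ValueError("omega and channels must be positive")
    proj = 4 * omega * channels * channels
    if mode == "dense":
        return proj + 2 * omega * omega * channels
    if mode == "windowed":
        if n_window is None or n_window < 1 or n_window > omega:
            raise ValueError("windowed mode needs 1 <= n_window <= omega")
        return proj + 2 * n_window * omega * channels
    raise ValueError(f"unknown mode: {mode}")
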