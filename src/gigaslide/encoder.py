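"""Tile embedding and the dilated-attention slide encoder.

The slide encoder is a pre-norm transformer over a slide's tile-embedding
sequence. Quadratic self-attention is replaced by dilated attention: the
sequence is partitioned into contiguous segments of length w; within a
segment every r-th position (one dilation phase per residue class) attends
only to positions of its own phase. Several (w, r) branches run in parallel
— small w with r = 1 for exact local context, large w with large r for
sparse global context — and per-position branch outputs are mixed with
weights proportional to each branch's softmax normalizer. Cost per branch is
O(N * w / r) instead of O(N^2).

A learned classification token at position 0 provides the global slide
embedding; discretized (col, row) tile coordinates are injected through two
learned lookup tables.

Tile embedding is pluggable. The bundled baseline embedder is deterministic:
channel-wise block statistics plus lagged horizontal difference statistics
(which expose local texture period), mapped through a fixed seeded random
projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (Embedding, LayerNorm, Linear, MLP, Module, ModuleList,
                 Tensor, concat, softmax, stack)
from .serialize import TileSequence

__all__ = [
    "DilatedConfig", "SlideEncoderConfig", "SlideRepresentation",
    "BaselineTileEmbedder", "embed_tiles", "dilated_attention",
    "SlideEncoder", "encode", "attention_score_ops",
]

# instrumentation: number of attention score entries computed (for complexity checks)
attention_score_ops = {"count": 0}


# --------------------------------------------------------------------- config
@dataclass(frozen=True)
class DilatedConfig:
    # (segment length w, dilation r); all phases of each branch are computed,
    # so every position is covered by every branch
    pairs: tuple[tuple[int, int], ...] = ((128, 1), (512, 4), (2048, 16))
    n_heads: int = 4
    head_assignment: str = "all-phases"

    def __post_init__(self):
        if not self.pairs:
            raise ValueError("at least one (w, r) pair required")
        ws = [w for w, _ in self.pairs]
        if ws != sorted(ws):
            raise ValueError("pairs must be sorted by increasing w")
        for w, r in self.pairs:
            if w % r != 0:
                raise ValueError(f"segment length {w} not divisible by dilation {r}")
        if not any(r == 1 for _, r in self.pairs):
            raise ValueError("at least one branch must have dilation 1")


@dataclass(frozen=True)
class SlideEncoderConfig:
    embed_dim: int = 64
    depth: int = 2
    n_heads: int = 4
    dilated: DilatedConfig = DilatedConfig()
    max_grid: int = 1000
    use_cls_token: bool = True
    input_dim: int | None = None  # project tile embeddings if != embed_dim

    def __post_init__(self):
        if self.embed_dim % self.n_heads != 0:
            raise ValueError("embed_dim must be divisible by n_heads")


@dataclass
class SlideRepresentation:
    contextual: np.ndarray  # N x D
    global_embedding: np.ndarray  # D


# ------------------------------------------------------------- tile embedding
class BaselineTileEmbedder:
    """Deterministic tile embedder: block statistics + texture-lag features
    through a fixed seeded Gaussian random projection.

    Features per RGB channel: mean and standard deviation over a grid of
    ``block_px`` blocks, plus the mean absolute horizontal difference at a
    set of pixel lags (a cheap texture-period signature).
    """

    def __init__(self, dim: int = 64, seed: int = 0, tile_px: int = 256,
                 block_px: int = 64, lags: tuple[int, ...] = (1, 2, 3, 4, 6, 8, 12, 16, 24, 32)):
        self.dim = dim
        self.tile_px = tile_px
        self.block_px = block_px
        self.lags = lags
        nb = (tile_px // block_px) ** 2
        n_feat = nb * 3 * 2 + len(lags) * 3
        rng = np.random.default_rng(seed)
        self._proj = rng.normal(0.0, 1.0 / np.sqrt(n_feat), size=(n_feat, dim))

    def features(self, tile: np.ndarray) -> np.ndarray:
        x = tile.astype(np.float64) / 255.0
        b = self.block_px
        n = self.tile_px // b
        blocks = x[: n * b, : n * b].reshape(n, b, n, b, 3)
        means = blocks.mean(axis=(1, 3)).ravel()
        stds = blocks.std(axis=(1, 3)).ravel()
        lag_prof = np.stack([np.abs(x[:, lag:] - x[:, :-lag]).mean(axis=(0, 1))
                             for lag in self.lags])  # (n_lags, 3)
        # normalize each channel's lag profile by its own mean: the profile
        # *shape* carries the texture period independently of tissue fraction
        lag_prof = lag_prof / (lag_prof.mean(axis=0, keepdims=True) + 1e-9)
        return np.concatenate([means, stds, lag_prof.ravel()])

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        return self.features(tile) @ self._proj


def embed_tiles(tiles, embedder) -> np.ndarray:
    """Embed each tile's raster; row i embeds tile i."""
    rows = []
    dim = None
    for t in tiles:
        v = np.asarray(embedder(t.pixels))
        if v.ndim != 1:
            raise ValueError("embedder must return a 1-D vector per tile")
        if dim is None:
            dim = v.shape[0]
        elif v.shape[0] != dim:
            raise ValueError(f"embedder output dimension mismatch: {v.shape[0]} != {dim}")
        rows.append(v)
    return np.stack(rows) if rows else np.zeros((0, 0))


# ---------------------------------------------------------- dilated attention
def _branch_attention(q: Tensor, k: Tensor, v: Tensor, valid: np.ndarray,
                      w: int, r: int) -> tuple[Tensor, Tensor]:
    """One (w, r) branch over batched sequences.

    q, k, v: (B, N, d) Tensors; valid: (N,) bool marking real positions.
    Returns (out (B, N, d), log_normalizer (B, N)).
    """
    B, N, d = q.shape
    P = int(np.ceil(N / w)) * w
    if P > N:
        pad = Tensor(np.zeros((B, P - N, d)))
        q, k, v = (concat([t, pad], axis=1) for t in (q, k, v))
    key_valid = np.zeros(P, dtype=bool)
    key_valid[:N] = valid
    n_seg, m = P // w, w // r

    def regroup(t: Tensor) -> Tensor:
        # (B, P, d) -> (B, n_seg, m, r, d) -> (B, n_seg, r, m, d) -> (G, m, d)
        return (t.reshape(B, n_seg, m, r, d)
                .transpose(0, 1, 3, 2, 4)
                .reshape(B * n_seg * r, m, d))

    qs, ks, vs = regroup(q), regroup(k), regroup(v)
    kv = (key_valid.reshape(n_seg, m, r).transpose(0, 2, 1)
          .reshape(n_seg * r, m))
    kv = np.broadcast_to(kv, (B, n_seg * r, m)).reshape(B * n_seg * r, m)

    scores = (qs @ ks.transpose(0, 2, 1)) * (1.0 / np.sqrt(d))
    attention_score_ops["count"] += scores.data.size
    mask = np.where(kv, 0.0, -1e30)[:, None, :]
    att = softmax(scores, axis=-1, additive_mask=mask)
    out = att @ vs

    # log softmax normalizer per query (branch mixing weight)
    shifted = scores + Tensor(mask)
    c = np.max(shifted.data, axis=-1, keepdims=True)  # constant shift
    logden = ((shifted - Tensor(c)).exp().sum(axis=-1)).log() + Tensor(c[..., 0])

    def ungroup(t: Tensor, dd: int) -> Tensor:
        return (t.reshape(B, n_seg, r, m, dd)
                .transpose(0, 1, 3, 2, 4)
                .reshape(B, P, dd))

    out = ungroup(out, d)[:, :N]
    logden = ungroup(logden.reshape(B * n_seg * r, m, 1), 1).reshape(B, P)[:, :N]
    return out, logden


def dilated_attention(q, k, v, cfg: DilatedConfig,
                      valid: np.ndarray | None = None):
    """Dilated multi-branch attention for one head group.

    q, k, v: (N, d) or (B, N, d) arrays or Tensors. ``valid`` optionally
    marks real (non-padding) positions; padding receives no attention mass
    and contributes none. Returns the same type as the input.
    """
    was_array = not isinstance(q, Tensor)
    q, k, v = Tensor._lift(q), Tensor._lift(k), Tensor._lift(v)
    squeezed = q.ndim == 2
    if squeezed:
        q, k, v = (t.reshape(1, *t.shape) for t in (q, k, v))
    B, N, d = q.shape
    if N == 0:
        raise ValueError("empty sequence")
    if valid is None:
        valid = np.ones(N, dtype=bool)

    outs, logdens = [], []
    for w, r in cfg.pairs:
        o, ld = _branch_attention(q, k, v, valid, min(w, int(np.ceil(N / r)) * r), r)
        outs.append(o)
        logdens.append(ld)
    if len(outs) == 1:
        result = outs[0]
    else:
        weights = softmax(stack(logdens, axis=0), axis=0)  # (n_branch, B, N)
        mixed = stack(outs, axis=0) * weights.reshape(len(outs), B, N, 1)
        result = mixed.sum(axis=0)
    if squeezed:
        result = result.reshape(N, d)
    return result.data if was_array else result


# -------------------------------------------------------------- slide encoder
class SelfAttention(Module):
    def __init__(self, dim: int, n_heads: int, dilated: DilatedConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.n_heads = n_heads
        self.dh = dim // n_heads
        self.dilated = dilated
        self.wq = Linear(dim, dim, rng)
        self.wk = Linear(dim, dim, rng)
        self.wv = Linear(dim, dim, rng)
        self.wo = Linear(dim, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        N, D = x.shape
        H, dh = self.n_heads, self.dh

        def heads(t: Tensor) -> Tensor:
            return t.reshape(N, H, dh).transpose(1, 0, 2)  # (H, N, dh)

        q, k, v = heads(self.wq(x)), heads(self.wk(x)), heads(self.wv(x))
        o = dilated_attention(q, k, v, self.dilated)
        o = o.transpose(1, 0, 2).reshape(N, D)
        return self.wo(o)


class Block(Module):
    """Pre-norm transformer block: LN -> attention -> +, LN -> MLP -> +."""

    def __init__(self, dim: int, n_heads: int, dilated: DilatedConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.ln1 = LayerNorm(dim)
        self.attn = SelfAttention(dim, n_heads, dilated, rng)
        self.ln2 = LayerNorm(dim)
        self.mlp = MLP(dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.ln1(x))
        return x + self.mlp(self.ln2(x))


class SlideEncoder(Module):
    def __init__(self, cfg: SlideEncoderConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        D = cfg.embed_dim
        if cfg.input_dim is not None and cfg.input_dim != D:
            self.input_proj = Linear(cfg.input_dim, D, rng)
        else:
            self.input_proj = None
        self.pos_col = Embedding(cfg.max_grid, D, rng)
        self.pos_row = Embedding(cfg.max_grid, D, rng)
        if cfg.use_cls_token:
            self.cls = Tensor(rng.normal(0, 0.02, size=(1, D)), requires_grad=True)
        self.blocks = ModuleList(
            Block(D, cfg.n_heads, cfg.dilated, rng) for _ in range(cfg.depth))

    def forward(self, embeddings, coords: np.ndarray) -> tuple[Tensor, Tensor | None]:
        """Returns (contextual (N, D) Tensor, global (D,) Tensor or None)."""
        coords = np.asarray(coords)
        if np.any(coords < 0) or np.any(coords >= self.cfg.max_grid):
            raise ValueError(f"coordinates outside [0, {self.cfg.max_grid})")
        x = Tensor._lift(embeddings)
        if self.input_proj is not None:
            x = self.input_proj(x)
        x = x + self.pos_col(coords[:, 0]) + self.pos_row(coords[:, 1])
        if self.cfg.use_cls_token:
            x = concat([self.cls, x], axis=0)
        for blk in self.blocks:
            x = blk(x)
        if self.cfg.use_cls_token:
            return x[1:], x[0]
        return x, None

    def encode(self, seq: TileSequence) -> SlideRepresentation:
        if seq.embeddings is None:
            raise ValueError("sequence has no tile embeddings")
        ctx, glob = self.forward(seq.embeddings, seq.coords)
        return SlideRepresentation(
            contextual=ctx.data.copy(),
            global_embedding=(glob.data.copy() if glob is not None
                              else ctx.data.mean(axis=0)))


def encode(seq: TileSequence, encoder: SlideEncoder) -> SlideRepresentation:
    return encoder.encode(seq)


def save_encoder(encoder: SlideEncoder, path) -> None:
    np.savez(path, **encoder.state_dict())


def load_encoder_state(path) -> dict[str, np.ndarray]:
    with np.load(path) as f:
        return {k: f[k] for k in f.files}
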