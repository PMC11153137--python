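"""Slide-level masked-autoencoder pretraining of the slide encoder.

Tile embeddings are precomputed and frozen; the slide encoder sees only the
visible subset of tiles (with their coordinates), a light decoder receives
the encoded visible tokens plus learned mask tokens carrying the masked
positions' coordinates, and the loss is the mean squared error between
decoder outputs and the frozen tile embeddings at masked positions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (AdamW, Embedding, LayerNorm, Linear, Module, ModuleList,
                 Tensor, concat, cosine_warmup_lr)
from .encoder import Block, SlideEncoder, SlideEncoderConfig
from .serialize import AugmentConfig, TileSequence, augment, slide_rng

__all__ = ["MAEConfig", "MaskPlan", "make_mask", "MAEDecoder", "mae_step",
           "pretrain", "PretrainResult"]


@dataclass(frozen=True)
class MAEConfig:
    mask_ratio: float = 0.75
    decoder_depth: int = 2
    decoder_dim: int = 64
    lr: float = 5e-4
    batch_slides: int = 4
    epochs: int = 30
    warmup_epochs: int = 1
    weight_decay: float = 0.05
    seed: int = 0
    augment: AugmentConfig | None = None  # applied once per slide per epoch

    def __post_init__(self):
        if not 0.0 < self.mask_ratio < 1.0:
            raise ValueError("mask_ratio must lie in (0, 1)")


@dataclass
class MaskPlan:
    masked_idx: np.ndarray
    visible_idx: np.ndarray


def make_mask(N: int, cfg: MAEConfig, rng: np.random.Generator) -> MaskPlan:
    """Uniform random mask without replacement; never masks everything."""
    if N < 2:
        raise ValueError("need at least 2 tiles to mask")
    n_mask = int(round(cfg.mask_ratio * N))
    if n_mask == 0 or n_mask == N:
        raise ValueError(f"mask_ratio {cfg.mask_ratio} degenerate for N={N}")
    perm = rng.permutation(N)
    return MaskPlan(masked_idx=np.sort(perm[:n_mask]),
                    visible_idx=np.sort(perm[n_mask:]))


class MAEDecoder(Module):
    """Light transformer decoder reconstructing masked tile embeddings."""

    def __init__(self, enc_cfg: SlideEncoderConfig, cfg: MAEConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        D, Dd = enc_cfg.embed_dim, cfg.decoder_dim
        out_dim = enc_cfg.input_dim or enc_cfg.embed_dim
        self.embed = Linear(D, Dd, rng)
        self.mask_token = Tensor(rng.normal(0, 0.02, size=(1, Dd)), requires_grad=True)
        self.pos_col = Embedding(enc_cfg.max_grid, Dd, rng)
        self.pos_row = Embedding(enc_cfg.max_grid, Dd, rng)
        self.blocks = ModuleList(
            Block(Dd, enc_cfg.n_heads, enc_cfg.dilated, rng)
            for _ in range(cfg.decoder_depth))
        self.norm = LayerNorm(Dd)
        self.head = Linear(Dd, out_dim, rng)

    def __call__(self, encoded_visible: Tensor, visible_coords: np.ndarray,
                 masked_coords: np.ndarray,
                 encoded_cls: Tensor | None = None) -> Tensor:
        """Returns reconstructions at the masked positions (n_masked, out_dim).

        When the encoder exposes a classification token its encoding is
        prepended as an extra (position-free) decoder token, so the global
        summary receives a direct reconstruction gradient.
        """
        n_vis = len(visible_coords)
        vis = self.embed(encoded_visible)
        msk = concat([self.mask_token] * len(masked_coords), axis=0)
        coords = np.concatenate([visible_coords, masked_coords])
        x = concat([vis, msk], axis=0)
        x = x + self.pos_col(coords[:, 0]) + self.pos_row(coords[:, 1])
        n_extra = 0
        if encoded_cls is not None:
            x = concat([self.embed(encoded_cls.reshape(1, -1)), x], axis=0)
            n_extra = 1
        for blk in self.blocks:
            x = blk(x)
        return self.head(self.norm(x[n_extra + n_vis:]))


def mae_step(seq: TileSequence, plan: MaskPlan, encoder: SlideEncoder,
             decoder: MAEDecoder) -> Tensor:
    """One reconstruction loss evaluation (differentiable scalar).

    The encoder sees visible tiles only; targets are the frozen input tile
    embeddings at masked positions; the loss averages over masked positions.
    """
    emb = np.asarray(seq.embeddings)
    vis_ctx, cls = encoder.forward(emb[plan.visible_idx], seq.coords[plan.visible_idx])
    pred = decoder(vis_ctx, seq.coords[plan.visible_idx], seq.coords[plan.masked_idx],
                   encoded_cls=cls)
    target = Tensor(emb[plan.masked_idx])
    return ((pred - target) ** 2).mean()


@dataclass
class PretrainResult:
    encoder: SlideEncoder
    decoder: MAEDecoder
    loss_curve: list[float]


def pretrain(corpus: list[TileSequence], cfg: MAEConfig,
             enc_cfg: SlideEncoderConfig | None = None,
             encoder: SlideEncoder | None = None,
             checkpoint_dir=None,
             ) -> PretrainResult:
    """Masked-autoencoder pretraining over a corpus of tile sequences.

    Cosine-decay learning rate after a linear warmup of ``warmup_epochs``;
    batches of ``batch_slides`` slides accumulate gradients before each
    optimizer step. Returns the trained encoder and the per-epoch mean loss
    curve. Fully reproducible given ``cfg.seed``.
    """
    if not corpus:
        raise ValueError("empty pretraining corpus")
    if encoder is None:
        if enc_cfg is None:
            raise ValueError("pass enc_cfg or an encoder instance")
        encoder = SlideEncoder(enc_cfg, seed=cfg.seed)
    enc_cfg = encoder.cfg
    decoder = MAEDecoder(enc_cfg, cfg, seed=cfg.seed + 1)
    params = list(encoder.named_parameters().items()) + \
        list(decoder.named_parameters("decoder.").items())
    opt = AdamW([p for _, p in params], lr=cfg.lr, weight_decay=cfg.weight_decay)

    rng = np.random.default_rng(cfg.seed)
    steps_per_epoch = max(1, int(np.ceil(len(corpus) / cfg.batch_slides)))
    total_steps = cfg.epochs * steps_per_epoch
    warmup_steps = cfg.warmup_epochs * steps_per_epoch

    curve: list[float] = []
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(corpus))
        losses = []
        for start in range(0, len(order), cfg.batch_slides):
            batch = order[start:start + cfg.batch_slides]
            opt.lr = cosine_warmup_lr(step, total_steps, cfg.lr, warmup_steps)
            opt.zero_grad()
            for si in batch:
                seq = corpus[si]
                if cfg.augment is not None:
                    seq = augment(seq, cfg.augment,
                                  rng=slide_rng(cfg.seed * 10007 + epoch, seq.slide_id))
                plan = make_mask(len(seq), cfg, rng)
                loss = mae_step(seq, plan, encoder, decoder)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"divergent loss at epoch {epoch}, slide {seq.slide_id}")
                (loss * (1.0 / len(batch))).backward()
                losses.append(float(loss.data))
            opt.step()
            step += 1
        curve.append(float(np.mean(losses)))
        if checkpoint_dir is not None:
            from pathlib import Path

            d = Path(checkpoint_dir)
            d.mkdir(parents=True, exist_ok=True)
            np.savez(d / f"epoch_{epoch:03d}.npz", **encoder.state_dict())
    return PretrainResult(encoder=encoder, decoder=decoder, loss_curve=curve)
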