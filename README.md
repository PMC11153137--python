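# gigaslide

Whole-slide image modeling at desk scale: a complete, testable
implementation of the two-stage "tiles → sequence" architecture used for
gigapixel pathology slides, with every training regime that makes it
useful — and a synthetic-slide generator so the entire stack runs and is
verified on a laptop, no proprietary data or GPUs required.

**Who it is for.** Researchers who want to study, extend or sanity-check
whole-slide modeling machinery — dilated attention over tile sequences,
slide-level masked-autoencoder pretraining, attention-MIL fine-tuning,
slide–report contrastive alignment — without standing up a hospital-scale
data pipeline first.

## The model

A slide is serialized into a row-major sequence of 256×256 px tiles at
0.5 µm/pixel (tiles below 0.1 tissue occupancy discarded, tissue found by
Otsu thresholding at a downsampled resolution). Each tile becomes an
embedding **x**ᵢ with integer grid coordinates (cᵢ, rᵢ) discretized on a
256 px grid. A pre-norm transformer with a classification token
contextualizes the sequence; its attention is *dilated*: for branches
(w, r) ∈ {(w₁,1), (w₂,r₂), …} the sequence is split into segments of
length w and, within a segment, positions of equal residue mod r attend
only to each other. Per-position branch outputs o⁽ᵇ⁾ᵢ are mixed by their
softmax normalizers Zᵢ⁽ᵇ⁾:

    oᵢ = Σ_b αᵢ⁽ᵇ⁾ o⁽ᵇ⁾ᵢ,   αᵢ⁽ᵇ⁾ = Zᵢ⁽ᵇ⁾ / Σ_b' Zᵢ⁽ᵇ'⁾

giving O(N·w/r) cost per branch instead of O(N²). Training regimes:

- **MAE pretraining** — mask 75% of tiles, reconstruct their frozen
  embeddings from the visible rest (MSE at masked positions only);
- **fine-tuning** — gated attention-MIL pooling over contextualized tiles,
  BCE/CE heads, one slide per patient (largest), 10-fold patient-level CV,
  batch 1 with 32-step gradient accumulation, 20 epochs;
- **vision–language** — symmetric InfoNCE between projected global slide
  embeddings and projected report embeddings; zero-shot classes scored by
  cosine similarity to averaged prompt embeddings over 50 random prompt
  draws.

There is no torch dependency: the training stack runs on a small
reverse-mode autodiff engine over numpy (`gigaslide.nn`), gradient-checked
against finite differences.

## Worked example

```python
import numpy as np
from gigaslide.fixtures import FixtureSpec, generate_slide
from gigaslide.preprocess import PreprocessConfig, preprocess_slide
from gigaslide.serialize import serialize
from gigaslide.encoder import (BaselineTileEmbedder, SlideEncoder,
                               SlideEncoderConfig, DilatedConfig, embed_tiles)

spec = FixtureSpec(image_height_px=768, image_width_px=768,
                   blob_radius_px=110, n_classes=3, seed=1)
slide = generate_slide(spec, label=0)          # striped-disk pseudo-slide, 1.0 MPP
tiles = preprocess_slide(slide.pixels, slide.mpp, PreprocessConfig(), "demo")
print(len(tiles), "tiles retained")            # -> 12 tiles retained

seq = serialize(tiles)                         # row-major (row, col) order
seq.embeddings = embed_tiles(tiles, BaselineTileEmbedder(dim=64, seed=0))

cfg = SlideEncoderConfig(embed_dim=64, depth=2, n_heads=4,
                         dilated=DilatedConfig(pairs=((8, 1), (32, 4))))
rep = SlideEncoder(cfg, seed=0).encode(seq)
print(rep.contextual.shape, rep.global_embedding.shape)  # -> (12, 64) (64,)
```

The 768² fixture at 1.0 MPP is upsampled ×2 to 0.5 MPP (1536², a 6×6 tile
grid); 12 of the 36 tiles pass the 0.1 occupancy filter, and the encoder
returns one contextualized embedding per tile plus the classification-token
slide embedding.

A shell interface wraps the same stages
(`gigaslide fixtures | tile | serialize | embed | pretrain | finetune |
vl-train | zeroshot`); see `gigaslide --help`.

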