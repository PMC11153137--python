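"""Slide-level vision-language alignment and zero-shot classification.

A learned linear projection maps the slide encoder's global (classification
token) embedding and a pluggable text encoder's report embedding into a
shared space; training minimizes the symmetric InfoNCE loss over the
in-batch similarity matrix of L2-normalized projections, scaled by a
learnable temperature. Zero-shot prediction renders prompt templates per
class, averages their projected text embeddings and softmaxes the cosine
similarities to the projected slide embedding; metrics are reported across
repeated random prompt draws (mean +/- s.e.m.), optionally aggregated by
majority vote.

The bundled test text encoder is a seeded bag-of-character-n-grams hashing
embedder, so the whole stage runs without any model downloads.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np

from .nn import AdamW, Linear, Module, Tensor, concat, cosine_warmup_lr, softmax, stack
from .encoder import SlideEncoder
from .serialize import TileSequence

__all__ = [
    "VLConfig", "PromptSet", "HashingTextEncoder", "VLStates",
    "contrastive_train", "clip_loss", "zero_shot_classify", "zero_shot_mutation",
]


@dataclass(frozen=True)
class VLConfig:
    lr: float = 5e-4
    batch_pairs: int = 32
    epochs: int = 10
    warmup_iters: int = 100
    init_temperature: float = 0.07
    holdout_patient_fraction: float = 0.2
    proj_dim: int = 32
    seed: int = 0


@dataclass(frozen=True)
class PromptSet:
    class_names: tuple[str, ...]
    templates: tuple[str, ...]  # each contains one "{}" slot for the class name
    n_samplings: int = 50

    def render(self, name: str, template: str) -> str:
        prompt = template.format(name)
        if not prompt.strip():
            raise ValueError("rendered prompt is empty")
        return prompt


class HashingTextEncoder:
    """Deterministic character n-gram hashing embedder (signed feature hashing)."""

    def __init__(self, dim: int = 96, seed: int = 0, ngram_range=(3, 5)):
        self.dim = dim
        self.seed = seed
        self.ngram_range = ngram_range

    def __call__(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim)
        t = text.lower()
        for n in range(self.ngram_range[0], self.ngram_range[1] + 1):
            for i in range(len(t) - n + 1):
                h = zlib.crc32(f"{self.seed}|{t[i:i + n]}".encode())
                v[h % self.dim] += 1.0 if (h >> 16) & 1 else -1.0
        norm = np.linalg.norm(v)
        return v / norm if norm > 0 else v


class VLStates(Module):
    """Trainable alignment state: slide projection, text projection, temperature."""

    def __init__(self, slide_dim: int, text_dim: int, cfg: VLConfig):
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.slide_proj = Linear(slide_dim, cfg.proj_dim, rng)
        self.text_proj = Linear(text_dim, cfg.proj_dim, rng)
        self.log_temp = Tensor(np.array([np.log(cfg.init_temperature)]),
                               requires_grad=True)


def _l2norm(x: Tensor) -> Tensor:
    return x / ((x**2).sum(axis=-1, keepdims=True) + 1e-12).sqrt()


def clip_loss(slide_emb: Tensor, text_emb: Tensor, states: VLStates) -> Tensor:
    """Symmetric cross-entropy over the in-batch similarity matrix."""
    zi = _l2norm(states.slide_proj(slide_emb))
    zt = _l2norm(states.text_proj(text_emb))
    sim = (zi @ zt.transpose(1, 0)) / states.log_temp.exp()
    B = sim.shape[0]
    diag = (np.arange(B), np.arange(B))
    li = -(softmax(sim, axis=1)[diag] + 1e-12).log().mean()
    lt = -(softmax(sim, axis=0)[diag] + 1e-12).log().mean()
    return (li + lt) * 0.5


def _holdout_split(patient_ids: list[str], frac: float, seed: int):
    patients = sorted(set(patient_ids))
    rng = np.random.default_rng(seed)
    held = set(rng.permutation(patients)[: int(round(frac * len(patients)))])
    train = [i for i, p in enumerate(patient_ids) if p not in held]
    holdout = [i for i, p in enumerate(patient_ids) if p in held]
    return train, holdout


def contrastive_train(pairs: list[tuple[TileSequence, str]], cfg: VLConfig,
                      text_encoder, encoder: SlideEncoder,
                      patient_ids: list[str] | None = None,
                      ) -> tuple[VLStates, list[int], list[float]]:
    """Align slide and report embeddings with in-batch contrastive training.

    Patients in the holdout fraction are excluded from training (they are the
    zero-shot evaluation set). Both the slide encoder and the projections are
    updated; the text encoder's trainable part is its projection. Returns the
    trained states, holdout pair indices and the per-epoch loss curve.
    """
    ids = [s.slide_id for s, _ in pairs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate slides in training pairs")
    if patient_ids is None:
        patient_ids = ids
    train_idx, holdout_idx = _holdout_split(patient_ids,
                                            cfg.holdout_patient_fraction, cfg.seed)
    text_embs = {i: np.asarray(text_encoder(t)) for i, (_, t) in enumerate(pairs)}
    text_dim = len(next(iter(text_embs.values())))
    states = VLStates(encoder.cfg.embed_dim, text_dim, cfg)

    params = states.parameters() + encoder.parameters()
    opt = AdamW(params, lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    steps_per_epoch = max(1, int(np.ceil(len(train_idx) / cfg.batch_pairs)))
    total_steps = cfg.epochs * steps_per_epoch
    curve: list[float] = []
    step = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(order), cfg.batch_pairs):
            batch = order[start:start + cfg.batch_pairs]
            if len(batch) < 2:
                continue
            opt.lr = cosine_warmup_lr(step, total_steps, cfg.lr, cfg.warmup_iters)
            opt.zero_grad()
            slide_vecs = []
            for i in batch:
                seq, _ = pairs[i]
                _, glob = encoder.forward(np.asarray(seq.embeddings), seq.coords)
                slide_vecs.append(glob.reshape(1, -1))
            s_emb = concat(slide_vecs, axis=0)
            t_emb = Tensor(np.stack([text_embs[i] for i in batch]))
            loss = clip_loss(s_emb, t_emb, states)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1
        curve.append(float(np.mean(losses)) if losses else np.nan)
    return states, holdout_idx, curve


# ------------------------------------------------------------------ zero-shot
def _project_text(texts: list[str], text_encoder, states: VLStates) -> np.ndarray:
    emb = Tensor(np.stack([np.asarray(text_encoder(t)) for t in texts]))
    return _l2norm(states.text_proj(emb)).data


def _project_slide(seq: TileSequence, encoder: SlideEncoder,
                   states: VLStates) -> np.ndarray:
    _, glob = encoder.forward(np.asarray(seq.embeddings), seq.coords)
    return _l2norm(states.slide_proj(glob.reshape(1, -1))).data[0]


def zero_shot_classify(seq: TileSequence, prompt_set: PromptSet,
                       states: VLStates, encoder: SlideEncoder, text_encoder,
                       rng: np.random.Generator | None = None,
                       aggregate: str = "per-draw",
                       ) -> np.ndarray:
    """Class probabilities for one slide under random prompt draws.

    Each of ``n_samplings`` draws samples a random template subset, averages
    each class's projected prompt embeddings, and softmaxes cosine
    similarities against the projected slide embedding. Returns an
    (n_samplings, n_classes) array; with ``aggregate='vote'`` a one-hot
    majority-vote distribution instead.
    """
    if len(prompt_set.class_names) < 2:
        raise ValueError("need at least 2 classes")
    if not prompt_set.templates:
        raise ValueError("empty prompt set")
    rng = rng or np.random.default_rng(0)
    z = _project_slide(seq, encoder, states)
    n_t = len(prompt_set.templates)
    probs = np.zeros((prompt_set.n_samplings, len(prompt_set.class_names)))
    for d in range(prompt_set.n_samplings):
        k = int(rng.integers(1, n_t + 1))
        chosen = rng.choice(n_t, size=k, replace=False)
        sims = []
        for name in prompt_set.class_names:
            texts = [prompt_set.render(name, prompt_set.templates[j]) for j in chosen]
            zt = _project_text(texts, text_encoder, states).mean(axis=0)
            zt = zt / (np.linalg.norm(zt) + 1e-12)
            sims.append(float(z @ zt))
        e = np.exp(np.array(sims) / 0.07)
        probs[d] = e / e.sum()
    if aggregate == "vote":
        votes = np.bincount(probs.argmax(axis=1), minlength=probs.shape[1])
        out = np.zeros(probs.shape[1])
        out[votes.argmax()] = 1.0
        return out[None, :]
    return probs


def zero_shot_mutation(seq: TileSequence, genes: list[str], states: VLStates,
                       encoder: SlideEncoder, text_encoder,
                       mutant_template: str = "{} mutated.",
                       wildtype_template: str = "{} wild-type.",
                       ) -> dict[str, float]:
    """Per-gene probability of mutation: two-way softmax over similarities to
    the rendered mutant and wild-type prompts."""
    z = _project_slide(seq, encoder, states)
    out = {}
    for gene in genes:
        zm = _project_text([mutant_template.format(gene)], text_encoder, states)[0]
        zw = _project_text([wildtype_template.format(gene)], text_encoder, states)[0]
        e = np.exp(np.array([z @ zm, z @ zw]) / 0.07)
        out[gene] = float(e[0] / e.sum())
    return out
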