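"""Fine-tuning and evaluation over slide representations.

Contextualized tile embeddings from the slide encoder are pooled with a
gated attention-MIL layer (two-branch tanh/sigmoid scoring, softmax weights
over tiles), then a linear head predicts per-gene mutation status
(multi-label, binary cross-entropy per label) or a cancer subtype
(multiclass, cross-entropy). Evaluation follows the standard protocol:
one slide per patient (the largest), patient-level stratified k-fold
cross-validation, AUROC / AUPRC / balanced accuracy / precision / F1 with
macro averages over labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn import metrics as skm
from sklearn.model_selection import StratifiedKFold

from .nn import AdamW, Linear, Module, Tensor, concat, cosine_warmup_lr, sigmoid, softmax
from .encoder import SlideEncoder
from .serialize import TileSequence

__all__ = [
    "FinetuneConfig", "TaskDataset", "ABMILPool", "abmil_pool",
    "select_largest_wsi", "make_folds", "finetune", "finetune_cv", "evaluate",
]


@dataclass(frozen=True)
class FinetuneConfig:
    base_lr: float = 2e-3
    weight_decay: float = 0.01
    layer_lr_decay: float | None = None
    epochs: int = 20
    batch_slides: int = 1
    grad_accum_steps: int = 32
    freeze_slide_encoder: bool = False
    use_tile_shortcut: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.grad_accum_steps < 1:
            raise ValueError("grad_accum_steps must be >= 1")


@dataclass
class TaskDataset:
    slides: list[TileSequence]
    labels: np.ndarray  # (n,) int for multiclass; (n, L) 0/1 for multilabel
    patient_ids: list[str]
    task_kind: str  # "multilabel" | "multiclass"

    def __post_init__(self):
        if self.task_kind not in ("multilabel", "multiclass"):
            raise ValueError(f"unknown task_kind {self.task_kind!r}")
        if len({p for p in self.patient_ids}) != len(self.patient_ids):
            raise ValueError("expected exactly one slide per patient")


# ------------------------------------------------------------------ pooling
class ABMILPool(Module):
    """Gated attention-MIL pooling: softmax attention weights over tiles."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.v = Linear(dim, hidden, rng)
        self.u = Linear(dim, hidden, rng)
        self.w = Linear(hidden, 1, rng, bias=False)

    def __call__(self, h: Tensor) -> tuple[Tensor, Tensor]:
        scores = self.w(self.v(h).tanh() * sigmoid(self.u(h)))  # (N, 1)
        weights = softmax(scores.transpose(1, 0), axis=-1)  # (1, N)
        pooled = (weights @ h).reshape(h.shape[-1])
        return pooled, weights.reshape(h.shape[0])


def abmil_pool(contextual: np.ndarray, pool: ABMILPool | None = None,
               seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Pool per-tile embeddings into one slide vector; returns (vector, weights)."""
    contextual = np.asarray(contextual)
    if pool is None:
        pool = ABMILPool(contextual.shape[1], max(8, contextual.shape[1] // 2),
                         np.random.default_rng(seed))
    vec, w = pool(Tensor(contextual))
    return vec.data.copy(), w.data.copy()


# --------------------------------------------------------------- cohort prep
def select_largest_wsi(cohort: pd.DataFrame) -> pd.DataFrame:
    """One slide per patient: maximal width*height, ties broken by slide_id."""
    df = cohort.copy()
    df["_area"] = df["width"] * df["height"]
    df = df.sort_values(["patient_id", "_area", "slide_id"],
                        ascending=[True, False, True], kind="mergesort")
    out = df.groupby("patient_id", sort=True).head(1).drop(columns="_area")
    return out.reset_index(drop=True)


def make_folds(labels: np.ndarray, patient_ids: list[str], k: int = 10,
               seed: int = 0) -> np.ndarray:
    """Patient-level stratified fold index per patient (deterministic).

    Multilabel targets are stratified on the tuple of labels. Classes with
    fewer members than k trigger a warning and best-effort stratification.
    """
    labels = np.asarray(labels)
    n = len(patient_ids)
    if n < k:
        raise ValueError(f"need at least k={k} patients, got {n}")
    strat = (labels if labels.ndim == 1
             else np.array([hash(tuple(row)) % (2**31) for row in labels]))
    _, counts = np.unique(strat, return_counts=True)
    if counts.min() < k:
        warnings.warn(f"a class has fewer than {k} members; stratification is best-effort")
        # StratifiedKFold refuses classes with < k members: fall back to
        # round-robin within class, which keeps per-fold counts within 1
        order = np.lexsort((np.arange(n), strat))
        folds = np.empty(n, dtype=int)
        rng = np.random.default_rng(seed)
        start = rng.integers(0, k)
        folds[order] = (np.arange(n) + start) % k
        return folds
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(n, dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(n), strat)):
        folds[test_idx] = f
    return folds


# -------------------------------------------------------------------- heads
class TaskHead(Module):
    """ABMIL pooling + linear classifier over (optionally shortcut) features."""

    def __init__(self, dim: int, n_out: int, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.pool = ABMILPool(dim, max(8, dim // 2), rng)
        self.fc = Linear(dim, n_out, rng)

    def __call__(self, features: Tensor) -> Tensor:
        pooled, _ = self.pool(features)
        return self.fc(pooled.reshape(1, -1)).reshape(-1)


def _slide_logits(seq: TileSequence, encoder: SlideEncoder, head: TaskHead,
                  cfg: FinetuneConfig) -> Tensor:
    emb = Tensor(np.asarray(seq.embeddings))
    ctx, _ = encoder.forward(emb, seq.coords)
    if cfg.freeze_slide_encoder:
        ctx = ctx.detach()
    if cfg.use_tile_shortcut:
        raw = emb if encoder.input_proj is None else encoder.input_proj(emb)
        ctx = concat([ctx, raw.detach()], axis=1)
    return head(ctx)


def _loss_fn(logits: Tensor, label, task_kind: str) -> Tensor:
    if task_kind == "multilabel":
        y = Tensor(np.asarray(label, dtype=float))
        p = sigmoid(logits)
        eps = 1e-9
        return -(y * (p + eps).log() + (1.0 - y) * (1.0 - p + eps).log()).mean()
    logp = softmax(logits.reshape(1, -1), axis=-1).reshape(-1)
    return -(logp[int(label)] + 1e-12).log()


def _predict_scores(seq, encoder, head, cfg, task_kind) -> np.ndarray:
    logits = _slide_logits(seq, encoder, head, cfg)
    if task_kind == "multilabel":
        return sigmoid(logits).data.copy()
    return softmax(logits.reshape(1, -1), axis=-1).data.reshape(-1).copy()


def _lr_scales(encoder: SlideEncoder, head: TaskHead, cfg: FinetuneConfig):
    """Parameter list + per-parameter lr multipliers (layer-wise decay)."""
    params, scales = [], []
    named = encoder.named_parameters()
    depth = len(encoder.blocks)
    for name, p in named.items():
        if cfg.freeze_slide_encoder:
            continue
        scale = 1.0
        if cfg.layer_lr_decay is not None:
            if name.startswith("blocks."):
                layer = int(name.split(".")[1])
                scale = cfg.layer_lr_decay ** (depth - layer)
            else:
                scale = cfg.layer_lr_decay ** (depth + 1)  # embeddings decay most
        params.append(p)
        scales.append(scale)
    for p in head.parameters():
        params.append(p)
        scales.append(1.0)
    return params, scales


def finetune(train: TaskDataset, encoder: SlideEncoder, cfg: FinetuneConfig,
             n_out: int) -> TaskHead:
    """Fine-tune the slide encoder (unless frozen) plus an ABMIL head.

    Batch size is one slide; gradients accumulate over ``grad_accum_steps``
    slides before each optimizer step, emulating that effective batch.
    """
    dim = encoder.cfg.embed_dim * (2 if cfg.use_tile_shortcut else 1)
    head = TaskHead(dim, n_out, seed=cfg.seed)
    params, scales = _lr_scales(encoder, head, cfg)
    opt = AdamW(params, lr=cfg.base_lr, weight_decay=cfg.weight_decay,
                lr_scales=scales)
    rng = np.random.default_rng(cfg.seed)
    n = len(train.slides)
    accum = cfg.grad_accum_steps
    steps_per_epoch = max(1, int(np.ceil(n / accum)))
    total_steps = cfg.epochs * steps_per_epoch
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, accum):
            batch = order[start:start + accum]
            opt.lr = cosine_warmup_lr(step, total_steps, cfg.base_lr,
                                      warmup_steps=steps_per_epoch)
            opt.zero_grad()
            for i in batch:
                loss = _loss_fn(_slide_logits(train.slides[i], encoder, head, cfg),
                                train.labels[i], train.task_kind)
                (loss * (1.0 / len(batch))).backward()
            opt.step()
            step += 1
    return head


def finetune_cv(dataset: TaskDataset, encoder_state: dict[str, np.ndarray],
                enc_cfg, cfg: FinetuneConfig, k: int = 10,
                ) -> tuple[pd.DataFrame, dict]:
    """Patient-level k-fold cross-validation with the standard protocol.

    Each fold re-initializes the encoder from ``encoder_state``, fine-tunes
    on the training patients and scores the held-out patients. Returns
    per-fold metric rows and a mean +/- s.e.m. summary.
    """
    labels = np.asarray(dataset.labels)
    folds = make_folds(labels, dataset.patient_ids, k=k, seed=cfg.seed)
    n_out = (labels.shape[1] if dataset.task_kind == "multilabel"
             else int(labels.max()) + 1)
    rows = []
    for f in range(k):
        test_mask = folds == f
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        # leakage guard: folds partition patients
        assert not set(np.array(dataset.patient_ids)[train_idx]) & \
            set(np.array(dataset.patient_ids)[test_idx])
        encoder = SlideEncoder(enc_cfg, seed=cfg.seed)
        encoder.load_state_dict(encoder_state)
        train = TaskDataset([dataset.slides[i] for i in train_idx],
                            labels[train_idx],
                            [dataset.patient_ids[i] for i in train_idx],
                            dataset.task_kind)
        head = finetune(train, encoder, cfg, n_out)
        scores = np.stack([_predict_scores(dataset.slides[i], encoder, head,
                                           cfg, dataset.task_kind)
                           for i in test_idx])
        m = evaluate(scores, labels[test_idx], dataset.task_kind)
        m["fold"] = f
        rows.append(m)
    df = pd.DataFrame(rows)
    summary = {}
    for c in df.columns:
        if c == "fold":
            continue
        vals = df[c].dropna().to_numpy(dtype=float)
        if len(vals):
            summary[c] = {"mean": float(np.mean(vals)),
                          "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                          if len(vals) > 1 else 0.0}
    return df, summary


# ------------------------------------------------------------------- metrics
def _binary_metrics(y: np.ndarray, s: np.ndarray) -> dict:
    if len(np.unique(y)) < 2:
        warnings.warn("single-class label column: AUROC/AUPRC undefined")
        return {"auroc": np.nan, "auprc": np.nan}
    return {"auroc": float(skm.roc_auc_score(y, s)),
            "auprc": float(skm.average_precision_score(y, s))}


def evaluate(scores: np.ndarray, labels: np.ndarray, task_kind: str) -> dict:
    """AUROC (rank statistic), AUPRC (step-interpolated average precision),
    balanced accuracy, precision, F1; macro averages over labels for
    multilabel, skipping undefined columns with a warning."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if task_kind == "multilabel":
        per = [_binary_metrics(labels[:, j], scores[:, j])
               for j in range(labels.shape[1])]
        pred = (scores >= 0.5).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bacc = np.mean([skm.balanced_accuracy_score(labels[:, j], pred[:, j])
                            for j in range(labels.shape[1])])
            prec = skm.precision_score(labels, pred, average="macro", zero_division=0)
            f1 = skm.f1_score(labels, pred, average="macro", zero_division=0)
        aurocs = [m["auroc"] for m in per if np.isfinite(m["auroc"])]
        auprcs = [m["auprc"] for m in per if np.isfinite(m["auprc"])]
        return {"macro_auroc": float(np.mean(aurocs)) if aurocs else np.nan,
                "macro_auprc": float(np.mean(auprcs)) if auprcs else np.nan,
                "balanced_accuracy": float(bacc),
                "precision": float(prec), "f1": float(f1)}
    # multiclass
    pred = scores.argmax(axis=1)
    n_classes = scores.shape[1]
    present = np.unique(labels)
    if len(present) < 2:
        auroc = auprc = np.nan
        warnings.warn("single-class test fold: AUROC/AUPRC undefined")
    else:
        onehot = np.eye(n_classes)[labels]
        cols = [j for j in range(n_classes) if len(np.unique(onehot[:, j])) == 2]
        auroc = float(np.mean([skm.roc_auc_score(onehot[:, j], scores[:, j])
                               for j in cols]))
        auprc = float(np.mean([skm.average_precision_score(onehot[:, j], scores[:, j])
                               for j in cols]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {"auroc": auroc, "auprc": auprc,
                "balanced_accuracy": float(skm.balanced_accuracy_score(labels, pred)),
                "precision": float(skm.precision_score(labels, pred, average="macro",
                                                       zero_division=0)),
                "f1": float(skm.f1_score(labels, pred, average="macro",
                                         zero_division=0))}
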