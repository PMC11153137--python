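"""Attention-MIL pooling, cohort utilities, metrics oracles, fine-tune contracts."""

import numpy as np
import pandas as pd
import pytest

from gigaslide.downstream import (ABMILPool, FinetuneConfig, TaskDataset,
                                  abmil_pool, evaluate, finetune, make_folds,
                                  select_largest_wsi)
from gigaslide.encoder import DilatedConfig, SlideEncoder, SlideEncoderConfig
from gigaslide.nn import cosine_warmup_lr
from gigaslide.serialize import TileSequence

ENC_CFG = SlideEncoderConfig(embed_dim=16, depth=1, n_heads=2,
                             dilated=DilatedConfig(pairs=((8, 1),)), max_grid=60)


# ------------------------------------------------------------------- ABMIL
def test_single_instance_pool_is_identity_with_unit_weight():
    x = np.random.default_rng(0).normal(size=(1, 8))
    vec, w = abmil_pool(x, seed=1)
    assert np.allclose(vec, x[0])
    assert w.shape == (1,) and w[0] == pytest.approx(1.0)


def test_identical_rows_give_uniform_weights():
    x = np.tile(np.random.default_rng(1).normal(size=(1, 8)), (5, 1))
    vec, w = abmil_pool(x, seed=2)
    assert np.allclose(w, 0.2)
    assert np.allclose(vec, x[0])


def test_pooled_vector_is_convex_combination_of_rows():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(6, 4))
    vec, w = abmil_pool(x, seed=3)
    assert w.sum() == pytest.approx(1.0)
    assert np.all(w >= 0)
    # solve the implied convex combination: weights recovered by least squares
    assert np.allclose(w @ x, vec)


# ----------------------------------------------------------- largest slide
def test_select_largest_wsi_identity_and_max_area():
    df = pd.DataFrame({
        "slide_id": ["a1", "a2", "b1"],
        "patient_id": ["A", "A", "B"],
        "label": [0, 0, 1],
        "width": [1024, 2048, 512],
        "height": [1024, 2048, 512],
    })
    out = select_largest_wsi(df)
    assert out["slide_id"].tolist() == ["a2", "b1"]


def test_select_largest_wsi_matches_bruteforce_on_random_cohort():
    rng = np.random.default_rng(4)
    rows = []
    for p in range(8):
        for s in range(int(rng.integers(1, 4))):
            rows.append({"slide_id": f"P{p}_S{s}", "patient_id": f"P{p}",
                         "label": p % 2, "width": int(rng.integers(100, 3000)),
                         "height": int(rng.integers(100, 3000))})
    df = pd.DataFrame(rows)
    out = select_largest_wsi(df)
    for p, grp in df.groupby("patient_id"):
        areas = grp["width"] * grp["height"]
        best = grp.loc[areas == areas.max()].sort_values("slide_id").iloc[0]
        assert out.loc[out.patient_id == p, "slide_id"].item() == best["slide_id"]


def test_select_largest_ties_broken_lexicographically():
    df = pd.DataFrame({"slide_id": ["z", "a"], "patient_id": ["P", "P"],
                       "label": [0, 0], "width": [10, 10], "height": [10, 10]})
    assert select_largest_wsi(df)["slide_id"].tolist() == ["a"]


# ------------------------------------------------------------------- folds
def test_balanced_folds_one_patient_per_class():
    labels = np.array([0, 1] * 10)
    pids = [f"P{i}" for i in range(20)]
    folds = make_folds(labels, pids, k=10, seed=0)
    for f in range(10):
        fl = labels[folds == f]
        assert len(fl) == 2 and set(fl) == {0, 1}


def test_folds_partition_and_stratification_tally():
    rng = np.random.default_rng(5)
    labels = rng.integers(0, 3, size=60)
    # ensure each class has >= 10 members for clean stratification
    labels[:30] = np.repeat([0, 1, 2], 10)
    pids = [f"P{i}" for i in range(60)]
    folds = make_folds(labels, pids, k=10, seed=1)
    assert sorted(np.unique(folds)) == list(range(10))
    assert len(folds) == 60
    for c in range(3):
        per_fold = [np.sum(labels[folds == f] == c) for f in range(10)]
        assert max(per_fold) - min(per_fold) <= 1


def test_small_class_triggers_warning_but_partitions():
    labels = np.array([0] * 18 + [1] * 2)
    pids = [f"P{i}" for i in range(20)]
    with pytest.warns(UserWarning):
        folds = make_folds(labels, pids, k=10, seed=0)
    assert len(folds) == 20
    assert sorted(np.unique(folds)) == list(range(10))


# ------------------------------------------------------------------ metrics
def test_perfect_separation_gives_unit_scores():
    m = evaluate(np.array([[0.9], [0.8], [0.1], [0.2]]),
                 np.array([[1], [1], [0], [0]]), "multilabel")
    assert m["macro_auroc"] == 1.0
    assert m["macro_auprc"] == 1.0


def test_auroc_equals_pair_counting_oracle():
    scores = np.array([0.1, 0.4, 0.35, 0.8])
    labels = np.array([0, 0, 1, 1])
    m = evaluate(scores[:, None], labels[:, None], "multilabel")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    conc = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    assert m["macro_auroc"] == pytest.approx(conc / (len(pos) * len(neg)))


def test_auroc_exhaustive_oracle_small_n():
    rng = np.random.default_rng(6)
    for _ in range(50):
        n = int(rng.integers(4, 13))
        labels = rng.integers(0, 2, size=n)
        if len(np.unique(labels)) < 2:
            continue
        scores = np.round(rng.random(n), 2)  # ties likely
        m = evaluate(scores[:, None], labels[:, None], "multilabel")
        pos, neg = scores[labels == 1], scores[labels == 0]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert m["macro_auroc"] == pytest.approx(u / (len(pos) * len(neg)))


def test_null_scores_auroc_near_half():
    rng = np.random.default_rng(7)
    n = 10_000
    scores = rng.random(n)
    labels = rng.integers(0, 2, size=n)
    m = evaluate(scores[:, None], labels[:, None], "multilabel")
    assert abs(m["macro_auroc"] - 0.5) < 0.02


def test_macro_of_identical_columns_equals_single_column():
    rng = np.random.default_rng(8)
    scores = rng.random(20)
    labels = rng.integers(0, 2, size=20)
    single = evaluate(scores[:, None], labels[:, None], "multilabel")
    triple = evaluate(np.tile(scores[:, None], (1, 3)),
                      np.tile(labels[:, None], (1, 3)), "multilabel")
    assert triple["macro_auroc"] == pytest.approx(single["macro_auroc"])


def test_single_class_column_undefined_with_warning():
    with pytest.warns(UserWarning):
        m = evaluate(np.array([[0.3], [0.6]]), np.array([[1], [1]]), "multilabel")
    assert np.isnan(m["macro_auroc"])


def test_multiclass_metrics_basic():
    scores = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
    m = evaluate(scores, np.array([0, 1, 2]), "multiclass")
    assert m["balanced_accuracy"] == 1.0
    assert m["auroc"] == 1.0


# ----------------------------------------------------------- finetune bits
def _dataset(n=6, dim=16):
    rng = np.random.default_rng(9)
    seqs, labels, pids = [], [], []
    for i in range(n):
        coords = np.unique(rng.integers(0, 50, size=(12, 2)), axis=0)[:5]
        order = np.lexsort((coords[:, 0], coords[:, 1]))
        seqs.append(TileSequence(f"P{i}_S0", coords[order],
                                 rng.normal(size=(5, dim)) + (i % 2)))
        labels.append(i % 2)
        pids.append(f"P{i}")
    return TaskDataset(seqs, np.array(labels), pids, "multiclass")


def test_frozen_encoder_state_unchanged_by_finetuning():
    ds = _dataset()
    enc = SlideEncoder(ENC_CFG, seed=0)
    before = enc.state_dict()
    cfg = FinetuneConfig(epochs=2, grad_accum_steps=3, freeze_slide_encoder=True,
                         seed=0)
    finetune(ds, enc, cfg, n_out=2)
    after = enc.state_dict()
    for k in before:
        assert np.array_equal(before[k], after[k]), k


def test_unfrozen_encoder_changes():
    ds = _dataset()
    enc = SlideEncoder(ENC_CFG, seed=0)
    before = enc.state_dict()
    cfg = FinetuneConfig(epochs=1, grad_accum_steps=3, seed=0)
    finetune(ds, enc, cfg, n_out=2)
    assert any(not np.array_equal(before[k], v)
               for k, v in enc.state_dict().items())


def test_lr_schedule_matches_closed_form():
    base, total, warm = 2e-3, 200, 10
    for step in (0, 5, 9, 10, 105, 200):
        got = cosine_warmup_lr(step, total, base, warm)
        if step < warm:
            expect = base * (step + 1) / warm
        else:
            frac = min(max((step - warm) / (total - warm), 0.0), 1.0)
            expect = base * 0.5 * (1 + np.cos(np.pi * frac))
        assert got == pytest.approx(expect)


def test_one_slide_per_patient_enforced():
    ds = _dataset()
    with pytest.raises(ValueError):
        TaskDataset(ds.slides, ds.labels, ["P0"] * len(ds.slides), "multiclass")
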