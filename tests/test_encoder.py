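"""Tile embedder and dilated-attention slide encoder: oracle equivalence,
complexity contract, padding invariance, classification-token sensitivity."""

import numpy as np
import pytest

from gigaslide.encoder import (BaselineTileEmbedder, DilatedConfig,
                               SlideEncoder, SlideEncoderConfig,
                               attention_score_ops, dilated_attention,
                               embed_tiles)
from gigaslide.experiments import dense_mixed_oracle
from gigaslide.preprocess import TileRecord
from gigaslide.serialize import TileSequence


def _dense(q, k, v):
    sc = q @ k.T / np.sqrt(q.shape[1])
    e = np.exp(sc - sc.max(axis=1, keepdims=True))
    return (e / e.sum(axis=1, keepdims=True)) @ v


# ------------------------------------------------------------ tile embedding
def _tile(fill):
    return TileRecord("s", 0, 0, 1.0, pixels=np.full((256, 256, 3), fill, np.uint8))


def test_identical_tiles_embed_identically_and_deterministically():
    emb = BaselineTileEmbedder(dim=32, seed=1)
    rows = embed_tiles([_tile(100), _tile(100), _tile(30)], emb)
    assert np.array_equal(rows[0], rows[1])
    assert not np.array_equal(rows[0], rows[2])
    emb2 = BaselineTileEmbedder(dim=32, seed=1)
    assert np.array_equal(embed_tiles([_tile(100)], emb2)[0], rows[0])


def test_embedder_dimension_mismatch_rejected():
    calls = iter([np.zeros(8), np.zeros(9)])
    with pytest.raises(ValueError):
        embed_tiles([_tile(1), _tile(2)], lambda p: next(calls))


def test_two_class_fixture_tiles_linearly_separable():
    from sklearn.linear_model import LogisticRegression
    from gigaslide.fixtures import FixtureSpec, generate_slide
    from gigaslide.preprocess import PreprocessConfig, preprocess_slide

    spec = FixtureSpec(image_height_px=640, image_width_px=640, blob_radius_px=120,
                       n_blobs=3, n_classes=2, texture_period_by_class=(4, 24), seed=6)
    emb = BaselineTileEmbedder(dim=32, seed=0)
    X, y = [], []
    for i in range(8):
        lab = i % 2
        s = generate_slide(spec, lab, seed_override=200 + i)
        tiles = preprocess_slide(s.pixels, s.mpp, PreprocessConfig(), f"t{i}")
        X.append(embed_tiles(tiles, emb))
        y += [lab] * len(tiles)
    X, y = np.vstack(X), np.array(y)
    half = len(y) // 2
    clf = LogisticRegression(max_iter=3000).fit(X[:half], y[:half])
    assert clf.score(X[half:], y[half:]) > 0.8


# --------------------------------------------------------- dilated attention
def test_single_large_segment_equals_dense_attention():
    rng = np.random.default_rng(2)
    q, k, v = rng.normal(size=(3, 20, 8))
    out = dilated_attention(q, k, v, DilatedConfig(pairs=((64, 1),)))
    assert np.allclose(out, _dense(q, k, v), atol=1e-12)


def test_explicit_mask_oracle_n16():
    rng = np.random.default_rng(3)
    q, k, v = rng.normal(size=(3, 16, 8))
    cfg = DilatedConfig(pairs=((4, 1), (8, 2)))
    out = dilated_attention(q, k, v, cfg)
    exp = dense_mixed_oracle(q, k, v, cfg.pairs)
    assert np.allclose(out, exp, atol=1e-10)


def test_constant_value_rows_give_convex_combination():
    rng = np.random.default_rng(4)
    q, k = rng.normal(size=(2, 24, 6))
    v = np.tile(rng.normal(size=(1, 6)), (24, 1))
    out = dilated_attention(q, k, v, DilatedConfig(pairs=((8, 1), (24, 4))))
    assert np.allclose(out, v, atol=1e-10)


def test_random_configurations_match_oracle():
    from gigaslide.experiments import run_dilated_oracle

    res = run_dilated_oracle(seed=12, n_configs=40)
    assert res["max_abs_err"] < 1e-5
    assert res["dense_case_err"] < 1e-12


def test_padding_invariance():
    rng = np.random.default_rng(5)
    N, P, d = 11, 16, 8
    q, k, v = rng.normal(size=(3, N, d))
    cfg = DilatedConfig(pairs=((4, 1), (8, 2)))
    base = dilated_attention(q, k, v, cfg)
    qp = np.vstack([q, rng.normal(size=(P - N, d))])
    kp = np.vstack([k, rng.normal(size=(P - N, d))])
    vp = np.vstack([v, rng.normal(size=(P - N, d))])
    valid = np.zeros(P, dtype=bool)
    valid[:N] = True
    padded = dilated_attention(qp, kp, vp, cfg, valid=valid)
    assert np.allclose(padded[:N], base, atol=1e-6)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        DilatedConfig(pairs=((8, 3),))  # r does not divide w
    with pytest.raises(ValueError):
        DilatedConfig(pairs=((8, 2),))  # no r=1 branch
    with pytest.raises(ValueError):
        DilatedConfig(pairs=())
    with pytest.raises(ValueError):
        dilated_attention(np.zeros((0, 4)), np.zeros((0, 4)), np.zeros((0, 4)),
                          DilatedConfig(pairs=((4, 1),)))


def test_complexity_contract_subquadratic():
    """Score-entry count grows as O(N * sum(w/r)), not O(N^2)."""
    cfg = DilatedConfig(pairs=((8, 1), (32, 4)))
    d = 4
    counts = {}
    for N in (64, 256, 1024):
        q, k, v = np.random.default_rng(N).normal(size=(3, N, d))
        attention_score_ops["count"] = 0
        dilated_attention(q, k, v, cfg)
        counts[N] = attention_score_ops["count"]
        bound = N * sum(w * (w // r) // w for w, r in cfg.pairs) * 2  # pad slack
        assert counts[N] <= N * (8 + 8) * 2
        assert counts[N] < N**2  # never dense
    # linear scaling: 4x sequence -> ~4x work (not 16x)
    assert counts[1024] <= 4.5 * counts[256]


# -------------------------------------------------------------- slide encoder
TINY = SlideEncoderConfig(embed_dim=16, depth=2, n_heads=2,
                          dilated=DilatedConfig(pairs=((4, 1), (8, 2))),
                          max_grid=50)


def _random_seq(n, dim=16, seed=0, slide_id="s"):
    rng = np.random.default_rng(seed)
    coords = np.unique(rng.integers(0, 40, size=(n + 10, 2)), axis=0)[:n]
    order = np.lexsort((coords[:, 0], coords[:, 1]))
    return TileSequence(slide_id, coords[order], rng.normal(size=(n, dim)))


def test_depth_zero_returns_inputs_plus_positional_terms():
    cfg = SlideEncoderConfig(embed_dim=16, depth=0, n_heads=2,
                             dilated=DilatedConfig(pairs=((4, 1),)), max_grid=50)
    enc = SlideEncoder(cfg, seed=0)
    seq = _random_seq(6)
    rep = enc.encode(seq)
    expect = (seq.embeddings
              + enc.pos_col.table.data[seq.coords[:, 0]]
              + enc.pos_row.table.data[seq.coords[:, 1]])
    assert np.allclose(rep.contextual, expect, atol=1e-12)


def test_permutation_of_tiles_canonicalized_by_serialization():
    enc = SlideEncoder(TINY, seed=1)
    seq = _random_seq(8, seed=3)
    rep1 = enc.encode(seq)
    perm = np.random.default_rng(0).permutation(8)
    from gigaslide.serialize import serialize
    from gigaslide.preprocess import TileRecord as TR

    tiles = [TR("s", int(c), int(r), 1.0) for c, r in seq.coords[perm]]
    seq2 = serialize(tiles)
    seq2.embeddings = seq.embeddings[perm][np.lexsort(
        (seq.coords[perm][:, 0], seq.coords[perm][:, 1]))]
    rep2 = enc.encode(seq2)
    assert np.allclose(rep1.contextual, rep2.contextual, atol=1e-12)
    assert np.allclose(rep1.global_embedding, rep2.global_embedding, atol=1e-12)


def test_dilated_encoder_matches_dense_encoder_through_full_blocks():
    """N=12 toy sequence: dilated schedule vs single dense segment w >= N+1
    (the classification token included) give identical outputs when the
    dilated schedule covers everything."""
    seq = _random_seq(12, seed=5)
    dense_cfg = SlideEncoderConfig(embed_dim=16, depth=2, n_heads=2,
                                   dilated=DilatedConfig(pairs=((16, 1),)),
                                   max_grid=50)
    enc_dense = SlideEncoder(dense_cfg, seed=7)
    # same weights, dilated schedule degenerate to one segment of 16 >= 13
    alt_cfg = SlideEncoderConfig(embed_dim=16, depth=2, n_heads=2,
                                 dilated=DilatedConfig(pairs=((16, 1), (16, 1))),
                                 max_grid=50)
    enc_alt = SlideEncoder(alt_cfg, seed=0)
    enc_alt.load_state_dict(enc_dense.state_dict())
    r1, r2 = enc_dense.encode(seq), enc_alt.encode(seq)
    assert np.allclose(r1.contextual, r2.contextual, atol=1e-4)
    assert np.allclose(r1.global_embedding, r2.global_embedding, atol=1e-4)


def test_cls_token_sensitive_to_tile_changes_in_coverage():
    enc = SlideEncoder(TINY, seed=2)
    seq = _random_seq(6, seed=9)
    g1 = enc.encode(seq).global_embedding
    seq.embeddings = seq.embeddings.copy()
    # a single-component change (a whole-row constant shift would be
    # invisible to the pre-norm layer normalization)
    seq.embeddings[2, 0] += 1.0
    g2 = enc.encode(seq).global_embedding
    assert np.abs(g1 - g2).max() > 1e-6


def test_out_of_range_coordinates_rejected():
    enc = SlideEncoder(TINY, seed=0)
    seq = _random_seq(4)
    seq.coords = seq.coords + 100  # beyond max_grid=50
    with pytest.raises(ValueError):
        enc.encode(seq)


def test_state_dict_roundtrip_bit_exact():
    enc = SlideEncoder(TINY, seed=11)
    seq = _random_seq(5, seed=13)
    rep = enc.encode(seq)
    enc2 = SlideEncoder(TINY, seed=99)
    enc2.load_state_dict(enc.state_dict())
    rep2 = enc2.encode(seq)
    assert np.array_equal(rep.contextual, rep2.contextual)
    assert np.array_equal(rep.global_embedding, rep2.global_embedding)
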