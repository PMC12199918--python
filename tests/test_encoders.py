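"""GCN propagation and Transformer encoder against hand-rolled oracles."""

import numpy as np
import pytest

from lmipredict._autodiff import Tensor
from lmipredict.encoders import (
    GcnBranch,
    TransformerBranch,
    init_transformer_layer,
    multi_head_attention,
    normalize_adjacency,
    pool_tokens,
    transformer_encoder,
    transformer_layer,
)
from lmipredict.seq_encoding import encode_records
from lmipredict.similarity import SimilarityMatrix


def _sim(values):
    n = len(values)
    return SimilarityMatrix([f"e{i}" for i in range(n)], np.asarray(values, float), "gip")


# -------------------------------------------------------------- adjacency
def test_normalize_adjacency_diagonal_graph_is_identity():
    out = normalize_adjacency(_sim(np.eye(3)))
    np.testing.assert_allclose(out, np.eye(3), atol=1e-12)


def test_normalize_adjacency_two_node_hand_example():
    # S' = I + S has rows summing to 3 -> D = 3I -> S'/3
    out = normalize_adjacency(_sim([[1.0, 1.0], [1.0, 1.0]]))
    np.testing.assert_allclose(out, [[2 / 3, 1 / 3], [1 / 3, 2 / 3]], atol=1e-12)


def test_normalize_adjacency_spectral_radius_at_most_one(rng):
    for n in (5, 20, 50):
        X = rng.random((n, n))
        V = np.clip((X + X.T) / 2, 0, 1)
        np.fill_diagonal(V, 1.0)
        out = normalize_adjacency(_sim(V))
        np.testing.assert_allclose(out, out.T, atol=1e-12)
        lam = np.linalg.eigvalsh(out).max()
        assert lam <= 1 + 1e-9


# ------------------------------------------------------------------- GCN
def _gcn_oracle(graphs, branch):
    """Dense numpy forward without the autodiff engine."""
    outs = []
    for g, Ws in zip(graphs, branch.weights):
        Sp = np.eye(len(g.ids)) + g.values
        d = Sp.sum(axis=1)
        A = Sp / np.sqrt(np.outer(d, d))
        H = g.values.copy()
        for W in Ws:
            H = np.maximum(A @ H @ W.data.astype(float), 0.0)
        outs.append(H)
    return outs


def test_gcn_forward_zero_weights_give_zero_channels(rng):
    graphs = [_sim(np.eye(4)) for _ in range(3)]
    branch = GcnBranch(4, "lncRNA", rng, n_layers=2, dim=8, dtype=np.float64)
    for Ws in branch.weights:
        for W in Ws:
            W.data[:] = 0.0
    out = branch.forward(graphs)
    for ch in out.channels:
        np.testing.assert_array_equal(ch.data, 0.0)


def test_gcn_single_layer_identity_weight_recovers_input(rng):
    # S = 0 off-diagonal -> normalized adjacency = I; W = I -> relu(L0) = L0
    graphs = [_sim(np.eye(5)) for _ in range(3)]
    branch = GcnBranch(5, "lncRNA", rng, n_layers=1, dim=5, dtype=np.float64)
    for Ws in branch.weights:
        Ws[0].data[:] = np.eye(5)
    out = branch.forward(graphs)
    for g, ch in zip(graphs, out.channels):
        np.testing.assert_allclose(ch.data, g.values, atol=1e-12)


def test_gcn_forward_matches_dense_oracle(rng):
    for n in (3, 6):
        graphs = []
        for _ in range(3):
            X = rng.random((n, n))
            V = np.clip((X + X.T) / 2, 0, 1)
            np.fill_diagonal(V, 1.0)
            graphs.append(_sim(V))
        branch = GcnBranch(n, "miRNA", rng, n_layers=2, dim=7, dtype=np.float64)
        out = branch.forward(graphs)
        expected = _gcn_oracle(graphs, branch)
        for ch, exp in zip(out.channels, expected):
            np.testing.assert_allclose(ch.data, exp, atol=1e-6)


def test_gcn_forward_requires_matching_ids(rng):
    g1 = _sim(np.eye(3))
    g2 = SimilarityMatrix(["x0", "x1", "x2"], np.eye(3), "gip")
    branch = GcnBranch(3, "lncRNA", rng)
    with pytest.raises(ValueError, match="share entity ids"):
        branch.forward([g1, g2, g1])


# --------------------------------------------------------------- attention
def test_attention_rows_sum_to_one_via_uniform_case(rng):
    # Wq = 0 -> uniform attention -> every output row equals the mean of X Wv
    p = init_transformer_layer(rng, 6, 1, 8, np.float64)
    p["Wq"].data[:] = 0.0
    p["Wo"].data[:] = np.eye(6)
    X = Tensor(rng.standard_normal((3, 6)))
    out = multi_head_attention(X, p).data
    expected = np.tile((X.data @ p["Wv"].data[0]).mean(axis=0), (3, 1))
    np.testing.assert_allclose(out, expected, atol=1e-12)


def test_single_head_attention_matches_closed_form(rng):
    dmodel = 6
    p = init_transformer_layer(rng, dmodel, 1, 8, np.float64)
    X = rng.standard_normal((4, dmodel))
    out = multi_head_attention(Tensor(X), p).data
    # independent closed form
    Q, K, V = (X @ p[w].data[0] for w in ("Wq", "Wk", "Wv"))
    logits = Q @ K.T / np.sqrt(dmodel)
    A = np.exp(logits - logits.max(axis=1, keepdims=True))
    A /= A.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(out, (A @ V) @ p["Wo"].data, atol=1e-10)


def test_attention_is_permutation_equivariant(rng):
    p = init_transformer_layer(rng, 8, 2, 16, np.float64)
    X = rng.standard_normal((5, 8))
    perm = rng.permutation(5)
    out = multi_head_attention(Tensor(X), p).data
    out_p = multi_head_attention(Tensor(X[perm]), p).data
    np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


def test_transformer_encoder_permutation_equivariance_depends_on_pe(rng):
    layers = [init_transformer_layer(rng, 8, 2, 16, np.float64) for _ in range(2)]
    X = rng.standard_normal((6, 8))
    perm = rng.permutation(6)
    out = transformer_encoder(Tensor(X), layers).data
    out_p = transformer_encoder(Tensor(X[perm]), layers).data
    np.testing.assert_allclose(out_p, out[perm], atol=1e-8)

    from lmipredict.seq_encoding import positional_table

    pe = positional_table(6, 8).table
    with_pe = transformer_encoder(Tensor(X + pe), layers).data
    with_pe_perm = transformer_encoder(Tensor(X[perm] + pe), layers).data
    assert not np.allclose(with_pe_perm, with_pe[perm], atol=1e-6)


def test_layer_norm_standardizes_rows(rng):
    X = Tensor(rng.standard_normal((4, 10)) * 5 + 3)
    g = Tensor(np.ones(10))
    b = Tensor(np.zeros(10))
    out = X.layer_norm(g, b).data
    np.testing.assert_allclose(out.mean(axis=-1), 0.0, atol=1e-5)
    np.testing.assert_allclose(out.var(axis=-1), 1.0, atol=1e-4)


def test_transformer_layer_with_zero_weights_is_double_layer_norm(rng):
    p = init_transformer_layer(rng, 8, 2, 16, np.float64)
    for k in ("Wq", "Wk", "Wv", "Wo", "W1", "W2"):
        p[k].data[:] = 0.0
    X = Tensor(rng.standard_normal((5, 8)))
    out = transformer_layer(X, p).data
    g = Tensor(np.ones(8))
    b = Tensor(np.zeros(8))
    expected = X.layer_norm(g, b).layer_norm(g, b).data
    np.testing.assert_allclose(out, expected, atol=1e-10)


def test_transformer_encoder_numerically_stable_under_large_inputs(rng):
    layers = [init_transformer_layer(rng, 8, 2, 16, np.float64) for _ in range(2)]
    X = Tensor(rng.standard_normal((7, 8)) * 1e3)
    out = transformer_encoder(X, layers).data
    assert np.isfinite(out).all()


# ----------------------------------------------------------------- pooling
def test_pool_tokens_reductions(rng):
    x = rng.standard_normal((2, 1, 4))
    np.testing.assert_allclose(pool_tokens(Tensor(x)).data, x[:, 0])
    v = rng.standard_normal(4)
    both = np.stack([np.stack([v, -v])])
    np.testing.assert_allclose(pool_tokens(Tensor(both)).data, 0.0, atol=1e-15)
    const = np.tile(v, (3, 5, 1))
    np.testing.assert_allclose(pool_tokens(Tensor(const)).data, np.tile(v, (3, 1)))


# ------------------------------------------------------------------ branch
def _encodings(records, aligned_len):
    from lmipredict.seq_encoding import scale_lengths

    L_k = scale_lengths(aligned_len)
    return {k: encode_records(records, k, L_k[k]) for k in (2, 3, 4)}


def test_transformer_branch_contract(lnc_records, rng):
    enc = _encodings(lnc_records, 16)
    branch = TransformerBranch("lncRNA", 16, np.random.default_rng(5),
                               dmodel=8, n_layers=1, n_head=2, ffn_dim=16,
                               dtype=np.float64)
    out = branch.forward(enc)
    assert len(out.channels) == 3
    assert all(c.shape == (len(lnc_records), 8) for c in out.channels)
    # deterministic under fixed params
    out2 = branch.forward(enc)
    for a, b in zip(out.channels, out2.channels):
        np.testing.assert_array_equal(a.data, b.data)
    # distinct k channels differ (no accidental weight sharing)
    assert not np.allclose(out.channels[0].data, out.channels[1].data)
    with pytest.raises(ValueError, match="missing k scales"):
        branch.forward({2: enc[2], 3: enc[3]})


def test_stacked_scales_equal_independent_per_scale_encoders(lnc_records):
    """The jointly-batched scale computation must match running each scale's
    own weights through the encoder one at a time."""
    from lmipredict.seq_encoding import embed_tokens

    branch = TransformerBranch("lncRNA", 14, np.random.default_rng(9),
                               dmodel=8, n_layers=2, n_head=2, ffn_dim=12,
                               dtype=np.float64)
    enc = _encodings(lnc_records, 14)
    fused = branch.forward(enc)
    for si, k in enumerate(branch.k_scales):
        X = embed_tokens(enc[k], branch.embeddings[k], branch.pe)
        layers = [branch.scale_layer(si, li) for li in range(len(branch.layers))]
        expected = pool_tokens(transformer_encoder(X, layers)).data
        np.testing.assert_allclose(fused.channels[si].data, expected, atol=1e-10)
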