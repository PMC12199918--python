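"""Feature-extraction branches: GCN over refined similarity graphs and a
Transformer encoder over multiscale k-mer encodings.

Each RNA class gets three GCN channels (one per similarity view) and three
Transformer channels (one per k scale).  Weights are not shared across
graphs, k scales, or RNA classes.

GCN propagation uses the renormalized adjacency
``D^{-1/2} (I + S) D^{-1/2}`` with the refined similarity rows themselves as
the parameter-free initial node features, two layers, and ReLU.

The Transformer layer is the standard post-norm encoder:
``X' = LN(X + MHA(X))``; ``out = LN(X' + ReLU(X' W1 + b1) W2 + b2)``,
with per-head scaled dot-product attention.  Per-entity vectors are obtained
by mean pooling over positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, glorot, stack
from .seq_encoding import K_SCALES, embed_tokens, positional_table


@dataclass
class ViewFeatures:
    channels: list  # 3 Tensors, entities x dmodel
    view: str  # "gcn" | "transformer"
    rna_class: str

    def __post_init__(self):
        shapes = {tuple(c.shape) for c in self.channels}
        if len(shapes) != 1:
            raise ValueError("view channels must share shape")


def normalize_adjacency(S) -> np.ndarray:
    """Symmetric renormalization D^{-1/2} (I + S) D^{-1/2} of a similarity graph."""
    V = S.values if hasattr(S, "values") else np.asarray(S, dtype=float)
    if not np.allclose(V, V.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    if V.min() < -1e-12:
        raise ValueError("similarity matrix must be non-negative")
    Sp = np.eye(V.shape[0]) + V
    d = Sp.sum(axis=1)
    dinv = 1.0 / np.sqrt(d)
    return dinv[:, None] * Sp * dinv[None, :]


class GcnBranch:
    """Independent multi-layer GCNs over three refined similarity graphs."""

    def __init__(self, n_nodes: int, rna_class: str, rng: np.random.Generator,
                 n_layers: int = 2, dim: int = 64, dtype=np.float32):
        self.rna_class = rna_class
        self.n_layers = n_layers
        self.dtype = dtype
        self.weights = []  # per graph: list of layer weight Tensors
        for _ in range(3):
            dims = [n_nodes] + [dim] * n_layers
            self.weights.append(
                [glorot(rng, (dims[l], dims[l + 1]), dtype) for l in range(n_layers)]
            )

    def parameters(self):
        return [w for graph in self.weights for w in graph]

    def forward(self, graphs) -> ViewFeatures:
        """graphs: three refined SimilarityMatrix objects sharing ids."""
        if len(graphs) != 3:
            raise ValueError("expected 3 similarity graphs")
        ids0 = list(graphs[0].ids)
        if any(list(g.ids) != ids0 for g in graphs[1:]):
            raise ValueError("similarity graphs must share entity ids")
        channels = []
        for g, Ws in zip(graphs, self.weights):
            A = Tensor(normalize_adjacency(g).astype(self.dtype))
            H = Tensor(g.values.astype(self.dtype))  # L^(0): refined similarity rows
            for W in Ws:
                H = (A @ H @ W).relu()
            channels.append(H)
        return ViewFeatures(channels, "gcn", self.rna_class)


# --------------------------------------------------------------- transformer
def multi_head_attention(X: Tensor, params: dict) -> Tensor:
    """Scaled dot-product multi-head self-attention.

    X is (..., positions, dmodel); params holds stacked per-head projections
    Wq, Wk, Wv of shape (..., heads, dmodel, d_k) and the output projection
    Wo of shape (..., dmodel, dmodel); leading parameter axes (e.g. a k-scale
    axis) broadcast against X's leading axes.
    """
    n_head, dmodel, d_k = params["Wq"].shape[-3:]
    lead = X.shape[:-2]
    P = X.shape[-2]

    def project(W):
        # fold the head axis into one gemm, then split it back out
        Wf = W.swapaxes(-3, -2).reshape(*W.shape[:-3], dmodel, n_head * d_k)
        return (X @ Wf).reshape(*lead, P, n_head, d_k).swapaxes(-3, -2)

    Q = project(params["Wq"]) * (1.0 / np.sqrt(d_k))  # scale Q, not the P x P scores
    K = project(params["Wk"])
    V = project(params["Wv"])
    ctx = (Q @ K.swapaxes(-1, -2)).softmax(axis=-1) @ V  # (..., n_head, P, d_k)
    heads = ctx.swapaxes(-3, -2).reshape(*lead, P, n_head * d_k)
    return heads @ params["Wo"]


def transformer_layer(X: Tensor, params: dict) -> Tensor:
    Xp = (X + multi_head_attention(X, params)).layer_norm(params["ln1_g"], params["ln1_b"])
    ffn = (Xp @ params["W1"] + params["b1"]).relu() @ params["W2"] + params["b2"]
    return (Xp + ffn).layer_norm(params["ln2_g"], params["ln2_b"])


def transformer_encoder(X: Tensor, layers) -> Tensor:
    for params in layers:
        X = transformer_layer(X, params)
    return X


def pool_tokens(encoded: Tensor) -> Tensor:
    """Arithmetic mean over the position axis -> entities x dmodel."""
    if encoded.shape[-2] < 1:
        raise ValueError("empty position axis")
    return encoded.mean(axis=-2)


def init_transformer_layer(rng, dmodel: int, n_head: int, ffn_dim: int, dtype) -> dict:
    if dmodel % n_head != 0:
        raise ValueError("n_head must divide dmodel")
    d_k = dmodel // n_head
    one = np.ones(dmodel, dtype=dtype)
    zero = np.zeros(dmodel, dtype=dtype)
    return {
        "Wq": glorot(rng, (n_head, dmodel, d_k), dtype),
        "Wk": glorot(rng, (n_head, dmodel, d_k), dtype),
        "Wv": glorot(rng, (n_head, dmodel, d_k), dtype),
        "Wo": glorot(rng, (dmodel, dmodel), dtype),
        "W1": glorot(rng, (dmodel, ffn_dim), dtype),
        "b1": Tensor(np.zeros(ffn_dim, dtype=dtype), requires_grad=True),
        "W2": glorot(rng, (ffn_dim, dmodel), dtype),
        "b2": Tensor(zero.copy(), requires_grad=True),
        "ln1_g": Tensor(one.copy(), requires_grad=True),
        "ln1_b": Tensor(zero.copy(), requires_grad=True),
        "ln2_g": Tensor(one.copy(), requires_grad=True),
        "ln2_b": Tensor(zero.copy(), requires_grad=True),
    }


def init_stacked_layer(rng, n_scales: int, dmodel: int, n_head: int,
                       ffn_dim: int, dtype) -> dict:
    """Per-scale transformer weights stacked along a leading scale axis.

    Nothing is shared between scales; stacking lets all scales run as one
    batched op over activations of shape (scale, entity*pos, d).
    """
    per = [init_transformer_layer(rng, dmodel, n_head, ffn_dim, dtype)
           for _ in range(n_scales)]
    out = {}
    for key in per[0]:
        data = np.stack([p[key].data for p in per])  # (S, ...) per-scale weights
        if data.ndim == 2:  # biases / layer-norm params: (S, 1, width)
            data = data[:, None]
        out[key] = Tensor(data, requires_grad=True)
    return out


def stacked_transformer_layer(X: Tensor, params: dict, n_entities: int, n_pos: int) -> Tensor:
    """One encoder layer over (scale, entity*pos, d) activations.

    Identical math to `transformer_layer` with per-scale weights; attention
    runs within each entity's token block only.  Flattening the entity and
    position axes keeps every projection, FFN matmul, and weight gradient a
    single large gemm per scale.
    """
    S = X.shape[0]
    n_head, dmodel, d_k = params["Wq"].shape[-3:]

    def project(W):
        Wf = W.swapaxes(-3, -2).reshape(S, dmodel, n_head * d_k)
        return (X @ Wf).reshape(S, n_entities, n_pos, n_head, d_k).swapaxes(-3, -2)

    Q = project(params["Wq"]) * (1.0 / np.sqrt(d_k))
    K = project(params["Wk"])
    V = project(params["Wv"])
    ctx = (Q @ K.swapaxes(-1, -2)).softmax(axis=-1) @ V  # (S, E, H, P, d_k)
    heads = ctx.swapaxes(-3, -2).reshape(S, n_entities * n_pos, dmodel)
    att = heads @ params["Wo"]
    Xp = (X + att).layer_norm(params["ln1_g"], params["ln1_b"])
    ffn = (Xp @ params["W1"] + params["b1"]).relu() @ params["W2"] + params["b2"]
    return (Xp + ffn).layer_norm(params["ln2_g"], params["ln2_b"])


class TransformerBranch:
    """Token embedding + Transformer encoder + mean pooling per k scale.

    One embedding table and one weight set per k in (2, 3, 4); the scales
    share no parameters but are evaluated jointly along a stacked scale axis.
    Scale k consumes sequences aligned to P + k - 1 so every scale yields the
    same token count P (one positional table for all).
    """

    def __init__(self, rna_class: str, aligned_len: int, rng: np.random.Generator,
                 dmodel: int = 64, n_layers: int = 2, n_head: int = 4,
                 ffn_dim: int = 128, dtype=np.float32, k_scales=K_SCALES):
        from .seq_encoding import scale_lengths

        self.rna_class = rna_class
        self.dmodel = dmodel
        self.dtype = dtype
        self.k_scales = tuple(k_scales)
        self.n_positions = scale_lengths(aligned_len, self.k_scales)[min(self.k_scales)] - min(self.k_scales) + 1
        self.pe = positional_table(self.n_positions, dmodel)
        self.embeddings = {k: glorot(rng, (4 ** k, dmodel), dtype) for k in self.k_scales}
        self.layers = [
            init_stacked_layer(rng, len(self.k_scales), dmodel, n_head, ffn_dim, dtype)
            for _ in range(n_layers)
        ]

    def parameters(self):
        out = [self.embeddings[k] for k in self.k_scales]
        for layer in self.layers:
            out.extend(layer.values())
        return out

    def scale_layer(self, scale_index: int, layer_index: int) -> dict:
        """One scale's weights of one layer, unstacked (for equivalence checks)."""
        raw = self.layers[layer_index]
        return {key: Tensor(raw[key].data[scale_index]) for key in raw}

    def forward(self, encodings: dict) -> ViewFeatures:
        """encodings: {k: KmerEncoding} for every configured k scale."""
        missing = [k for k in self.k_scales if k not in encodings]
        if missing:
            raise ValueError(f"missing k scales {missing}")
        per_scale = []
        for k in self.k_scales:
            if encodings[k].token_ids.shape[1] != self.n_positions:
                raise ValueError(
                    f"scale k={k}: expected {self.n_positions} tokens, "
                    f"got {encodings[k].token_ids.shape[1]}"
                )
            per_scale.append(embed_tokens(encodings[k], self.embeddings[k], self.pe))
        E, P = per_scale[0].shape[0], self.n_positions
        X = stack(per_scale, axis=0).reshape(len(self.k_scales), E * P, self.dmodel)
        for layer in self.layers:
            X = stacked_transformer_layer(X, layer, E, P)
        pooled = pool_tokens(X.reshape(len(self.k_scales), E, P, self.dmodel))
        return ViewFeatures([pooled[i] for i in range(len(self.k_scales))],
                            "transformer", self.rna_class)
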