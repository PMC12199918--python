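"""End-to-end interaction predictor as a scikit-learn style estimator.

``InteractionPredictor`` owns the entity-level data (sequence records and
expression profiles for both RNA classes) as constructor parameters and is
fit on ``X`` = an (n_pairs, 2) integer array of (lncRNA index, miRNA index)
with binary labels ``y``.  ``fit`` builds the three similarity graphs per
class (the GIP kernel sees only the training positives), refines them with
the p-nearest-neighbour rule, tokenizes sequences at k = 2, 3, 4, and
jointly trains the GCN branch, the Transformer branch, channel-attention
fusion, the contrastive projection heads, and the KAN scoring head against
the summed contrastive + BCE objective with Adam.

Training is full-graph by default (one optimizer step per epoch over all
training pairs): the entity embeddings are global functions of the shared
similarity graphs, so there is no stochastic minibatch to exploit at desk
scale.  Set ``batch_size`` for stochastic pair minibatches (the entity
forward pass is recomputed per step; the contrastive denominator always
spans the full entity set).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._autodiff import Adam, Tensor, concat, glorot
from .encoders import GcnBranch, TransformerBranch
from .fusion import ChannelAttention, contrastive_loss
from .predictor import KanNetwork, bce_loss, compute_metrics, score_pairs, summarize_reports, total_loss
from .seq_encoding import K_SCALES, encode_records, scale_lengths
from .similarity import expression_similarity, gip_similarity, pnn_refine, sequence_similarity


class InteractionPredictor(BaseEstimator, ClassifierMixin):
    """Multimodal contrastive lncRNA-miRNA interaction classifier.

    Parameters follow the method's defaults: 2 GCN layers, embedding width
    64, learning rate 1e-3, 100 epochs, temperature 0.5, p = 10 neighbours,
    decision threshold 0.5.  ``use_gcn`` / ``use_transformer`` /
    ``use_contrastive`` expose the single-branch and no-contrast ablations.
    """

    def __init__(self, lnc_records=None, mir_records=None,
                 lnc_profiles=None, mir_profiles=None,
                 p_neighbors=10, aligned_len=400, dmodel=64,
                 gcn_layers=2, transformer_layers=2, n_heads=4, ffn_dim=128,
                 kan_hidden=32, grid_size=5, spline_order=3, grid_range=(-2.0, 2.0),
                 temperature=0.5, learning_rate=1e-3, epochs=100, batch_size=128,
                 use_gcn=True, use_transformer=True, use_contrastive=True,
                 dtype="float32", random_state=0, verbose=0):
        self.lnc_records = lnc_records
        self.mir_records = mir_records
        self.lnc_profiles = lnc_profiles
        self.mir_profiles = mir_profiles
        self.p_neighbors = p_neighbors
        self.aligned_len = aligned_len
        self.dmodel = dmodel
        self.gcn_layers = gcn_layers
        self.transformer_layers = transformer_layers
        self.n_heads = n_heads
        self.ffn_dim = ffn_dim
        self.kan_hidden = kan_hidden
        self.grid_size = grid_size
        self.spline_order = spline_order
        self.grid_range = grid_range
        self.temperature = temperature
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.use_gcn = use_gcn
        self.use_transformer = use_transformer
        self.use_contrastive = use_contrastive
        self.dtype = dtype
        self.random_state = random_state
        self.verbose = verbose

    # ------------------------------------------------------------------ setup
    def _np_dtype(self):
        return np.dtype(self.dtype).type

    def _build_graphs(self, adjacency):
        """Refined similarity graphs per class; GIP from training adjacency."""
        p = self.p_neighbors
        lnc = [
            sequence_similarity(self.lnc_records),
            expression_similarity(self.lnc_profiles),
            gip_similarity(adjacency, "lnc", ids=[r.id for r in self.lnc_records]),
        ]
        mir = [
            sequence_similarity(self.mir_records),
            expression_similarity(self.mir_profiles),
            gip_similarity(adjacency, "mir", ids=[r.id for r in self.mir_records]),
        ]
        lnc = [pnn_refine(S, min(p, len(S.ids) - 1)) for S in lnc]
        mir = [pnn_refine(S, min(p, len(S.ids) - 1)) for S in mir]
        return lnc, mir

    def _forward(self):
        """One full entity-level forward pass; returns (L*, M*, l_con)."""
        parts_l, parts_m = [], []
        views = {}
        if self.use_gcn:
            views["lnc_gcn"] = self._gcn_lnc.forward(self._lnc_graphs)
            views["mir_gcn"] = self._gcn_mir.forward(self._mir_graphs)
            parts_l.append(self._att["lnc_gcn"].forward(views["lnc_gcn"].channels))
            parts_m.append(self._att["mir_gcn"].forward(views["mir_gcn"].channels))
        if self.use_transformer:
            views["lnc_trans"] = self._trans_lnc.forward(self._lnc_enc)
            views["mir_trans"] = self._trans_mir.forward(self._mir_enc)
            parts_l.append(self._att["lnc_trans"].forward(views["lnc_trans"].channels))
            parts_m.append(self._att["mir_trans"].forward(views["mir_trans"].channels))
        L = parts_l[0] if len(parts_l) == 1 else concat(parts_l, axis=1)
        M = parts_m[0] if len(parts_m) == 1 else concat(parts_m, axis=1)

        l_con = Tensor(np.asarray(0.0, dtype=self._np_dtype()))
        if self.use_contrastive and self.use_gcn and self.use_transformer:
            z_gcn = concat(
                [parts_l[0] @ self._proj_gcn, parts_m[0] @ self._proj_gcn], axis=0
            )
            z_trans = concat(
                [parts_l[1] @ self._proj_trans, parts_m[1] @ self._proj_trans], axis=0
            )
            l_con = contrastive_loss(z_gcn, z_trans, self.temperature)
        return L, M, l_con

    # -------------------------------------------------------------------- fit
    def fit(self, X, y):
        X = np.asarray(X, dtype=int)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n_pairs, 2) array of entity indices")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        if not (self.use_gcn or self.use_transformer):
            raise ValueError("at least one branch must be enabled")
        dt = self._np_dtype()
        rng = np.random.default_rng(self.random_state)
        n_l, n_m = len(self.lnc_records), len(self.mir_records)

        adjacency = np.zeros((n_l, n_m))
        for (i, j), lab in zip(X, y):
            if lab == 1:
                adjacency[i, j] = 1.0

        if self.use_gcn:
            self._lnc_graphs, self._mir_graphs = self._build_graphs(adjacency)
            self._gcn_lnc = GcnBranch(n_l, "lncRNA", rng, self.gcn_layers, self.dmodel, dt)
            self._gcn_mir = GcnBranch(n_m, "miRNA", rng, self.gcn_layers, self.dmodel, dt)
        if self.use_transformer:
            L_k = scale_lengths(self.aligned_len)
            self._lnc_enc = {k: encode_records(self.lnc_records, k, L_k[k]) for k in K_SCALES}
            self._mir_enc = {k: encode_records(self.mir_records, k, L_k[k]) for k in K_SCALES}
            self._trans_lnc = TransformerBranch(
                "lncRNA", self.aligned_len, rng, self.dmodel, self.transformer_layers,
                self.n_heads, self.ffn_dim, dt)
            self._trans_mir = TransformerBranch(
                "miRNA", self.aligned_len, rng, self.dmodel, self.transformer_layers,
                self.n_heads, self.ffn_dim, dt)

        self._att = {}
        if self.use_gcn:
            self._att["lnc_gcn"] = ChannelAttention(rng, dt)
            self._att["mir_gcn"] = ChannelAttention(rng, dt)
        if self.use_transformer:
            self._att["lnc_trans"] = ChannelAttention(rng, dt)
            self._att["mir_trans"] = ChannelAttention(rng, dt)

        params = []
        if self.use_gcn:
            params += self._gcn_lnc.parameters() + self._gcn_mir.parameters()
        if self.use_transformer:
            params += self._trans_lnc.parameters() + self._trans_mir.parameters()
        for att in self._att.values():
            params += att.parameters()
        if self.use_contrastive and self.use_gcn and self.use_transformer:
            self._proj_gcn = glorot(rng, (self.dmodel, self.dmodel), dt)
            self._proj_trans = glorot(rng, (self.dmodel, self.dmodel), dt)
            params += [self._proj_gcn, self._proj_trans]

        in_dim = self.dmodel * 2 * (int(self.use_gcn) + int(self.use_transformer))
        self._kan = KanNetwork(in_dim, rng, self.kan_hidden, self.grid_range,
                               self.grid_size, self.spline_order, dt)
        params += self._kan.parameters()

        opt = Adam(params, lr=self.learning_rate)
        self.history_ = {"loss": [], "bce": [], "contrastive": []}
        n_pairs = X.shape[0]
        for epoch in range(self.epochs):
            if self.batch_size is None:
                batches = [np.arange(n_pairs)]
            else:
                order = rng.permutation(n_pairs)
                batches = [order[s:s + self.batch_size]
                           for s in range(0, n_pairs, self.batch_size)]
            ep_loss = ep_bce = ep_con = 0.0
            for b in batches:
                opt.zero_grad()
                L, M, l_con = self._forward()
                scores = score_pairs(L, M, X[b], self._kan)
                l_bce = bce_loss(y[b].astype(dt), scores)
                loss = total_loss(l_con, l_bce)
                loss.backward()
                opt.step()
                w = len(b) / n_pairs
                ep_loss += loss.item() * w
                ep_bce += l_bce.item() * w
                ep_con += l_con.item() * w
            self.history_["loss"].append(ep_loss)
            self.history_["bce"].append(ep_bce)
            self.history_["contrastive"].append(ep_con)
            if self.verbose and (epoch % 10 == 0 or epoch == self.epochs - 1):
                print(f"epoch {epoch:4d}  total {ep_loss:.4f}  bce {ep_bce:.4f}  con {ep_con:.4f}")

        L, M, _ = self._forward()
        self.lnc_embedding_ = L.data.copy()
        self.mir_embedding_ = M.data.copy()
        self.final_loss_ = self.history_["loss"][-1]
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        return self

    # ---------------------------------------------------------------- predict
    def predict_proba(self, X):
        X = np.asarray(X, dtype=int)
        s = score_pairs(Tensor(self.lnc_embedding_), Tensor(self.mir_embedding_),
                        X, self._kan).data
        return np.column_stack([1.0 - s, s])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.decision_function(X) > 0.5).astype(int)


# ------------------------------------------------------------------ protocol
def evaluate_fold(dataset, train_idx, val_idx, threshold=0.5, **est_params):
    """Fit on one fold's training pairs and score its validation pairs."""
    est = InteractionPredictor(
        lnc_records=dataset.lnc_records, mir_records=dataset.mir_records,
        lnc_profiles=dataset.lnc_profiles, mir_profiles=dataset.mir_profiles,
        **est_params)
    pairs = dataset.pair_indices
    labels = dataset.labels
    est.fit(pairs[train_idx], labels[train_idx])
    scores = est.decision_function(pairs[val_idx])
    return compute_metrics(labels[val_idx], scores, threshold), est


def cross_validate(dataset, plan, threshold=0.5, **est_params):
    """Run a SplitPlan end to end; returns (per-fold reports, summary dict).

    ``dataset`` bundles entity data and labelled pairs (``LabelledDataset``).
    Folds whose validation pairs are single-class are skipped (ranking
    metrics undefined there).
    """
    reports = []
    for tr, va in plan.folds:
        if len(np.unique(dataset.labels[va])) < 2:
            continue
        rep, _ = evaluate_fold(dataset, tr, va, threshold, **est_params)
        reports.append(rep)
    if not reports:
        raise ValueError("no fold had both classes in validation")
    return reports, summarize_reports(reports)


class LabelledDataset:
    """Entity data plus a ratio-controlled labelled pair set."""

    def __init__(self, lnc_records, mir_records, lnc_profiles, mir_profiles, interactions):
        self.lnc_records = list(lnc_records)
        self.mir_records = list(mir_records)
        self.lnc_profiles = list(lnc_profiles)
        self.mir_profiles = list(mir_profiles)
        self.interactions = interactions
        order_l = [r.id for r in self.lnc_records]
        order_m = [r.id for r in self.mir_records]
        if order_l != list(interactions.lnc_ids) or order_m != list(interactions.mir_ids):
            raise ValueError("entity ordering mismatch between records and interactions")
        self.pair_indices = interactions.pair_indices
        self.labels = interactions.labels
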