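"""Multichannel (squeeze-excitation) attention and cross-view contrastive loss.

Channel attention compresses each of the three feature channels to a scalar
by global average pooling, gates the channels through a two-layer
ReLU/sigmoid excitation network, rescales every channel by its gate, and
fuses the rescaled stack with a learnable 1x1 cross-channel convolution
(a weighted channel sum) into a single entities x dim matrix.

The contrastive loss treats the GCN view and the Transformer view of the
same entity as a positive pair.  Every entity in both views is an anchor;
for an anchor, the only positive is the same entity in the other view, and
the negatives are all other entities' vectors in both views (including
cross-class entities: lncRNA anchors see miRNA negatives).  Vectors are
L2-normalized so similarities are cosines, scaled by a temperature T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, glorot, stack
from .encoders import ViewFeatures

N_CHANNELS = 3


@dataclass
class FusedFeatures:
    """Per-class fused views and their GCN-then-Transformer concatenations."""

    lnc_gcn: Tensor
    lnc_trans: Tensor
    mir_gcn: Tensor
    mir_trans: Tensor

    @property
    def lnc(self) -> Tensor:  # L*: n_lnc x 128
        return concat([self.lnc_gcn, self.lnc_trans], axis=1)

    @property
    def mir(self) -> Tensor:  # M*: n_mir x 128
        return concat([self.mir_gcn, self.mir_trans], axis=1)


def squeeze(x) -> float:
    """Global average pool of one channel matrix to a scalar."""
    x = x.data if isinstance(x, Tensor) else np.asarray(x)
    if x.size == 0:
        raise ValueError("empty channel matrix")
    return float(x.mean())


class ChannelAttention:
    """Squeeze-excitation gate plus 1x1 cross-channel fusion for t=3 channels.

    No bottleneck is used in the excitation MLP: with only three channels a
    reduction ratio would be meaningless.
    """

    def __init__(self, rng: np.random.Generator, dtype=np.float32, t: int = N_CHANNELS):
        self.t = t
        self.W1 = glorot(rng, (t, t), dtype)
        self.W2 = glorot(rng, (t, t), dtype)
        self.fuse_weights = Tensor(np.full(t, 1.0 / t, dtype=dtype), requires_grad=True)

    def parameters(self):
        return [self.W1, self.W2, self.fuse_weights]

    def forward(self, channels) -> Tensor:
        """channels: t Tensors of shape m x n -> fused m x n Tensor."""
        if len(channels) != self.t:
            raise ValueError(f"expected {self.t} channels, got {len(channels)}")
        X = stack(channels, axis=0)  # t x m x n
        z = X.mean(axis=(1, 2)).reshape(self.t, 1)  # squeeze, per channel
        z_att = (self.W2 @ (self.W1 @ z).relu()).sigmoid()  # excitation gates in (0,1)
        scaled = X * z_att.reshape(self.t, 1, 1)
        return (scaled * self.fuse_weights.reshape(self.t, 1, 1)).sum(axis=0)


def channel_attention(channels, module: ChannelAttention) -> Tensor:
    return module.forward(channels)


def anchor_loss(cos_pos: float, cos_negs, temperature: float) -> float:
    """Single-anchor contrastive term: -log exp(s_p/T) / sum exp(s/T).

    The denominator runs over the positive and all negatives.  With no
    negatives the term is exactly zero.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    s = np.concatenate([[cos_pos], np.atleast_1d(np.asarray(cos_negs, dtype=float))]) / temperature
    m = s.max()
    return float(np.log(np.exp(s - m).sum()) + m - s[0])


def contrastive_loss(view_a: Tensor, view_b: Tensor, temperature: float = 0.5) -> Tensor:
    """Cross-view supervised contrastive loss, averaged over all 2E anchors.

    view_a / view_b are entities x d feature matrices with matched row order
    (typically lncRNAs and miRNAs stacked).  Each row of each view anchors
    one term whose positive is the same row in the other view and whose
    denominator contains every other vector of both views.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if view_a.shape != view_b.shape:
        raise ValueError("views must share shape")
    E = view_a.shape[0]
    for v in (view_a, view_b):
        norms = np.linalg.norm(v.data, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero feature vector cannot be L2-normalized")
    Z = concat([view_a.l2_normalize(), view_b.l2_normalize()], axis=0)  # 2E x d
    S = (Z @ Z.swapaxes(0, 1)) * (1.0 / temperature)
    mask = np.full((2 * E, 2 * E), 0.0, dtype=S.dtype)
    np.fill_diagonal(mask, -1e9)  # exclude the anchor itself from the denominator
    denom = (S + Tensor(mask)).logsumexp(axis=-1)  # 2E
    pos_idx = np.concatenate([np.arange(E) + E, np.arange(E)])
    pos = S[np.arange(2 * E), pos_idx]
    return (denom - pos).mean()


class ViewFusion:
    """Channel attention per (class, view) followed by fixed-order concatenation."""

    def __init__(self, rng: np.random.Generator, dtype=np.float32):
        self.lnc_gcn_att = ChannelAttention(rng, dtype)
        self.lnc_trans_att = ChannelAttention(rng, dtype)
        self.mir_gcn_att = ChannelAttention(rng, dtype)
        self.mir_trans_att = ChannelAttention(rng, dtype)

    def parameters(self):
        return (
            self.lnc_gcn_att.parameters()
            + self.lnc_trans_att.parameters()
            + self.mir_gcn_att.parameters()
            + self.mir_trans_att.parameters()
        )

    def forward(self, lnc_gcn: ViewFeatures, lnc_trans: ViewFeatures,
                mir_gcn: ViewFeatures, mir_trans: ViewFeatures) -> FusedFeatures:
        for a, b in ((lnc_gcn, lnc_trans), (mir_gcn, mir_trans)):
            if a.channels[0].shape[0] != b.channels[0].shape[0]:
                raise ValueError("entity count mismatch between views")
        return FusedFeatures(
            lnc_gcn=self.lnc_gcn_att.forward(lnc_gcn.channels),
            lnc_trans=self.lnc_trans_att.forward(lnc_trans.channels),
            mir_gcn=self.mir_gcn_att.forward(mir_gcn.channels),
            mir_trans=self.mir_trans_att.forward(mir_trans.channels),
        )


def fuse_views(gcn: ViewFeatures, trans: ViewFeatures, gcn_att: ChannelAttention,
               trans_att: ChannelAttention) -> Tensor:
    """Fuse one class's two views into its entities x 128 concatenation."""
    if gcn.channels[0].shape[0] != trans.channels[0].shape[0]:
        raise ValueError("entity count mismatch between views")
    return concat([gcn_att.forward(gcn.channels), trans_att.forward(trans.channels)], axis=1)
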