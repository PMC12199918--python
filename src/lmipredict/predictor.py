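"""KAN scoring head, training losses, and the evaluation metric suite.

A Kolmogorov-Arnold network (KAN) layer places a learnable univariate
function on every edge, parameterized as a residual base path plus a
B-spline: ``KAN(x) = W_base . SiLU(x) + W_spline . B(x)`` with ``B`` the
order-k B-spline basis over a fixed uniform grid.  Inputs are clamped to the
grid range so the basis always has support.  The pair score is the sigmoid
of the stacked KAN output on the concatenated lncRNA/miRNA embeddings, with
0.5 as the interaction decision threshold.

Training minimizes the unweighted sum of the cross-view contrastive loss
and the binary cross-entropy of the pair scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from ._autodiff import Tensor, glorot

EPS_PROB = 1e-7


# ------------------------------------------------------------------ B-splines
def make_knots(grid_range=(-2.0, 2.0), grid_size: int = 5, order: int = 3) -> np.ndarray:
    lo, hi = grid_range
    if not hi > lo:
        raise ValueError("grid range must be increasing")
    if order < 1 or grid_size < 1:
        raise ValueError("grid_size and spline order must be >= 1")
    h = (hi - lo) / grid_size
    return lo + h * np.arange(-order, grid_size + order + 1, dtype=float)


def bspline_basis(x: np.ndarray, knots: np.ndarray, order: int):
    """Cox-de Boor basis and its derivative at `x` (any shape).

    Returns (basis, dbasis), each of shape x.shape + (n_basis,) where
    n_basis = len(knots) - 1 - order.  On the interior of the grid the basis
    is a partition of unity.
    """
    t = np.asarray(knots, dtype=x.dtype)
    if np.any(np.diff(t) <= 0):
        raise ValueError("knot vector must be strictly increasing")
    xe = x[..., None]
    B = ((t[:-1] <= xe) & (xe < t[1:])).astype(x.dtype)
    dB = np.zeros_like(B[..., :-order]) if order else np.zeros_like(B)
    for k in range(1, order + 1):
        left_den = t[k:-1] - t[:-k - 1]
        right_den = t[k + 1:] - t[1:-k]
        if k == order:  # closed-form derivative from the order k-1 basis
            dB = k * (B[..., :-1] / left_den - B[..., 1:] / right_den)
        # in-place update: B_k[i] = (x-t_i)/ld * B[i] + (t_{i+k+1}-x)/rd * B[i+1]
        left = np.subtract(xe, t[:-k - 1])
        left /= left_den
        left *= B[..., :-1]
        right = np.subtract(t[k + 1:], xe)
        right /= right_den
        right *= B[..., 1:]
        left += right
        B = left
    return B, dB


def bspline_basis_tensor(x: Tensor, knots: np.ndarray, order: int) -> Tensor:
    """Autodiff wrapper around the B-spline basis (analytic derivative)."""
    B, dB = bspline_basis(x.data, knots, order)
    out = Tensor(B, x.requires_grad, (x,))
    if x.requires_grad:
        out._backward = lambda g: x._accum((g * dB).sum(axis=-1))
    return out


@dataclass
class KanLayer:
    """One KAN layer: SiLU base path plus per-edge B-spline path."""

    in_dim: int
    out_dim: int
    rng: np.random.Generator
    grid_range: tuple = (-2.0, 2.0)
    grid_size: int = 5
    order: int = 3
    dtype: type = np.float32

    def __post_init__(self):
        self.knots = make_knots(self.grid_range, self.grid_size, self.order)
        self.n_basis = len(self.knots) - 1 - self.order
        self.W_base = glorot(self.rng, (self.in_dim, self.out_dim), self.dtype)
        spline = glorot(self.rng, (self.in_dim * self.n_basis, self.out_dim), self.dtype)
        spline.data *= 0.1  # start near the base path
        self.W_spline = spline

    def parameters(self):
        return [self.W_base, self.W_spline]

    def forward(self, x: Tensor) -> Tensor:
        lo, hi = self.grid_range
        span = hi - lo
        xc = x.clip(lo, hi - 1e-6 * span)  # keep basis support at the top knot
        B = bspline_basis_tensor(xc, self.knots.astype(np.asarray(x.data).dtype), self.order)
        flat = B.reshape(*x.shape[:-1], self.in_dim * self.n_basis)
        return x.silu() @ self.W_base + flat @ self.W_spline


def kan_layer(x, layer: KanLayer):
    """Functional form of KanLayer.forward accepting arrays or Tensors."""
    t = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    return layer.forward(t)


class KanNetwork:
    """Stacked KAN layers ending in a single logit (widths in -> hidden -> 1)."""

    def __init__(self, in_dim: int, rng: np.random.Generator, hidden: int = 32,
                 grid_range=(-2.0, 2.0), grid_size: int = 5, order: int = 3,
                 dtype=np.float32):
        self.layers = [
            KanLayer(in_dim, hidden, rng, grid_range, grid_size, order, dtype),
            KanLayer(hidden, 1, rng, grid_range, grid_size, order, dtype),
        ]

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer.forward(x)
        return x


def score_pairs(lnc_emb: Tensor, mir_emb: Tensor, pairs: np.ndarray, kan: KanNetwork) -> Tensor:
    """Interaction probabilities for (lnc_index, mir_index) pairs.

    Concatenates the two 128-d embeddings per pair, runs the KAN, and applies
    a sigmoid; a pair is called interacting when the score exceeds 0.5.
    """
    from ._autodiff import concat

    pairs = np.asarray(pairs, dtype=int)
    x = concat([lnc_emb.take(pairs[:, 0]), mir_emb.take(pairs[:, 1])], axis=1)
    return kan.forward(x).reshape(-1).sigmoid()


def bce_loss(y, y_hat) -> Tensor:
    """Mean binary cross-entropy with probabilities clamped at 1e-7."""
    y = np.asarray(y, dtype=float)
    p = y_hat if isinstance(y_hat, Tensor) else Tensor(np.asarray(y_hat, dtype=float))
    if y.shape != p.shape:
        raise ValueError("label/score length mismatch")
    yd = y.astype(p.dtype)
    pc = p.clip(EPS_PROB, 1.0 - EPS_PROB)
    return -(Tensor(yd) * pc.log() + Tensor(1.0 - yd) * (1.0 - pc).log()).mean()


def total_loss(l_con, l_bce):
    """Unweighted sum of the contrastive and BCE terms."""
    return l_con + l_bce


# -------------------------------------------------------------------- metrics
@dataclass
class EvalReport:
    acc: float
    recall: float
    precision: float
    f1: float
    auc: float
    aupr: float
    tp: int
    fp: int
    tn: int
    fn: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("acc", "recall", "precision", "f1", "auc", "aupr", "tp", "fp", "tn", "fn")}


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    epochs: int = 100
    batch_size: int | None = None  # None: full-graph step per epoch
    seed: int = 0
    decision_threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def compute_metrics(labels, scores, threshold: float = 0.5) -> EvalReport:
    """Confusion-table metrics plus ROC-AUC and AUPR.

    AUC uses the trapezoidal ROC with rank-averaged ties; AUPR integrates the
    precision-recall step curve.  With a single class present the ranking
    metrics are undefined and raised as an error.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("label/score length mismatch")
    pred = (s > threshold).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    acc = (tp + tn) / y.size
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    if len(np.unique(y)) < 2:
        raise ValueError("AUC/AUPR undefined with a single class; "
                         f"threshold metrics: acc={acc:.4f}")
    auc = float(roc_auc_score(y, s))
    aupr = float(average_precision_score(y, s))
    return EvalReport(acc, recall, precision, f1, auc, aupr, tp, fp, tn, fn)


def summarize_reports(reports) -> dict:
    """Fold-wise mean and standard deviation for every metric."""
    keys = ("acc", "recall", "precision", "f1", "auc", "aupr")
    out = {}
    for k in keys:
        vals = np.array([getattr(r, k) for r in reports], dtype=float)
        out[f"{k}_mean"] = float(vals.mean())
        out[f"{k}_std"] = float(vals.std())
    return out
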