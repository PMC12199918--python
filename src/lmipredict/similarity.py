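"""Entity-entity similarity matrices and p-nearest-neighbour refinement.

Three similarity views are built per RNA class:

* sequence similarity, ``1 - lev(s_i, s_j) / max(|s_i|, |s_j|)`` with ``lev``
  the Levenshtein edit distance (max-length normalization keeps it in [0,1]);
* expression similarity, the Pearson correlation mapped through ``(1 + r)/2``
  so edge weights stay non-negative while preserving order;
* Gaussian interaction-profile (GIP) kernel similarity over rows/columns of
  the binary interaction matrix, with bandwidth normalized by the mean
  squared profile norm (gamma' = 1).

Each matrix can be sparsified by a mutual p-nearest-neighbour rule that keeps
an edge at full weight when both endpoints select each other, half weight
when only one does, and drops it otherwise — preserving symmetry, which the
GCN's symmetric normalization requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

SIM_KINDS = ("sequence", "expression", "gip")


@dataclass
class SimilarityMatrix:
    ids: list
    values: np.ndarray
    kind: str
    refined: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")
        if self.kind not in SIM_KINDS:
            raise ValueError(f"unknown similarity kind {self.kind!r}")

    def validate(self, tol: float = 1e-9) -> "SimilarityMatrix":
        v = self.values
        if not np.allclose(v, v.T, atol=tol):
            raise ValueError("similarity matrix not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=tol):
            raise ValueError("similarity diagonal != 1")
        if v.min() < -tol or v.max() > 1 + tol:
            raise ValueError("similarity entries outside [0, 1]")
        return self


def levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def sequence_similarity(records) -> SimilarityMatrix:
    """Pairwise normalized Levenshtein similarity, 1 - d / max(len)."""
    records = list(records)
    if not records:
        raise ValueError("empty record list")
    n = len(records)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = records[i].sequence, records[j].sequence
            S[i, j] = S[j, i] = 1.0 - levenshtein(a, b) / max(len(a), len(b))
    return SimilarityMatrix([r.id for r in records], S, "sequence").validate()


def expression_similarity(profiles) -> SimilarityMatrix:
    """(1 + Pearson r)/2; zero-variance profiles get 0 off-diagonal, 1 on it."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("empty profile list")
    C = len(profiles[0].values)
    if any(len(p.values) != C for p in profiles):
        raise ValueError("mismatched condition counts")
    X = np.vstack([p.values for p in profiles])
    sd = X.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(X)
    S = (1.0 + R) / 2.0
    S[degenerate, :] = 0.0
    S[:, degenerate] = 0.0
    np.fill_diagonal(S, 1.0)
    S = np.clip(S, 0.0, 1.0)  # guard fp wobble at r = +/-1
    return SimilarityMatrix([p.id for p in profiles], S, "expression").validate()


def gip_similarity(adjacency: np.ndarray, axis: str, ids=None) -> SimilarityMatrix:
    """Gaussian interaction-profile kernel over adjacency rows (lnc) or columns (mir).

    sim(i, j) = exp(-gamma * ||IP_i - IP_j||^2) with
    gamma = gamma' / mean_k ||IP_k||^2 and gamma' = 1.
    """
    A = np.asarray(adjacency, dtype=float)
    if axis not in ("lnc", "mir"):
        raise ValueError("axis must be 'lnc' or 'mir'")
    IP = A if axis == "lnc" else A.T
    n = IP.shape[0]
    mean_sq = float(np.mean(np.sum(IP ** 2, axis=1)))
    if mean_sq == 0:
        raise ValueError("all-zero adjacency: GIP bandwidth undefined")
    gamma = 1.0 / mean_sq
    sq = np.sum(IP ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * IP @ IP.T
    d2 = np.maximum(d2, 0.0)
    S = np.exp(-gamma * d2)
    np.fill_diagonal(S, 1.0)
    if ids is None:
        ids = [f"{axis}{i}" for i in range(n)]
    return SimilarityMatrix(list(ids), S, "gip").validate()


def pnn_refine(S: SimilarityMatrix, p: int) -> SimilarityMatrix:
    """Mutual p-nearest-neighbour sparsification.

    Edge (i, j) keeps weight S_ij when i and j are in each other's top-p
    neighbour sets (self excluded, ties by lower index), S_ij / 2 when only
    one selects the other, 0 otherwise.  The diagonal is forced to 1.
    """
    n = len(S.ids)
    if not 1 <= p <= n - 1:
        raise ValueError(f"p must be in [1, {n - 1}], got {p}")
    V = S.values
    member = np.zeros((n, n), dtype=bool)
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: (-V[i, j], j))
        member[i, order[:p]] = True
    weight = (member.astype(float) + member.T.astype(float)) / 2.0
    out = V * weight
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(list(S.ids), out, S.kind, refined=True).validate()


def write_similarity(path, S: SimilarityMatrix) -> None:
    pd.DataFrame(S.values, index=S.ids, columns=S.ids).to_csv(path, sep="\t", index_label="id")


def read_similarity(path, kind: str, refined: bool = False) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix([str(i) for i in df.index], df.to_numpy(dtype=float), kind, refined)
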