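"""Multiscale k-mer tokenization and sinusoidal positional encoding.

Sequences are first brought to a common aligned length by tiling (repeating
end-to-end) and truncating, then cut into overlapping stride-1 k-mers at
k = 2, 3, 4.  Each k-mer maps to an integer token in [0, 4^k) by base-4
encoding (A=0, C=1, G=2, U=3, most-significant first); the one-hot encoding
of tokens is realized downstream as an embedding lookup.  The positional
table follows the standard sine/cosine construction:

    PE[pos, 2a]   = sin(pos / 10000^(2a/dmodel))
    PE[pos, 2a+1] = cos(pos / 10000^(2a/dmodel))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
_INDEX_BASE = "ACGU"
K_SCALES = (2, 3, 4)


@dataclass
class KmerEncoding:
    k: int
    token_ids: np.ndarray  # entities x positions, int
    aligned_length: int
    rna_class: str
    ids: list

    def __post_init__(self):
        t = np.asarray(self.token_ids)
        if t.min(initial=0) < 0 or t.max(initial=0) >= 4 ** self.k:
            raise ValueError("token ids out of vocabulary range")
        if t.shape[1] != self.aligned_length - self.k + 1:
            raise ValueError("positions per entity must equal L - k + 1")


@dataclass
class PositionalEncoding:
    n_positions: int
    dmodel: int
    table: np.ndarray


def align_length(sequence: str, L: int) -> str:
    """Tile the sequence end-to-end until >= L, then truncate to exactly L."""
    if L < 1:
        raise ValueError("L must be >= 1")
    if not sequence:
        raise ValueError("empty sequence")
    reps = -(-L // len(sequence))  # ceil
    return (sequence * reps)[:L]


def kmerize(sequence: str, k: int) -> list:
    """Overlapping stride-1 k-mer token ids (base-4, most-significant first)."""
    if len(sequence) < k:
        raise ValueError(f"sequence of length {len(sequence)} shorter than k={k}")
    digits = np.array([_BASE_INDEX[c] for c in sequence], dtype=np.int64)
    weights = 4 ** np.arange(k - 1, -1, -1)
    n = len(sequence) - k + 1
    windows = np.lib.stride_tricks.sliding_window_view(digits, k)[:n]
    return list(windows @ weights)


def decode_kmer(token: int, k: int) -> str:
    """Inverse of the k-mer token mapping."""
    if not 0 <= token < 4 ** k:
        raise ValueError("token out of range")
    out = []
    for _ in range(k):
        out.append(_INDEX_BASE[token % 4])
        token //= 4
    return "".join(reversed(out))


def scale_lengths(aligned_len: int, k_scales=K_SCALES) -> dict:
    """Per-scale alignment lengths giving every scale the same token count.

    Aligning scale k to ``P + k - 1`` (P = aligned_len - max(k) + 1) makes all
    scales emit exactly P stride-1 k-mer tokens, so the three encoding
    matrices share one position axis (and one positional table).
    """
    kmax = max(k_scales)
    P = aligned_len - kmax + 1
    if P < 1:
        raise ValueError(f"aligned_len {aligned_len} too short for k={kmax}")
    return {k: P + k - 1 for k in k_scales}


def encode_records(records, k: int, L: int) -> KmerEncoding:
    """Tokenize a collection of records at one k, after length alignment."""
    records = list(records)
    tok = np.array([kmerize(align_length(r.sequence, L), k) for r in records], dtype=np.int64)
    return KmerEncoding(k, tok, L, records[0].rna_class, [r.id for r in records])


def positional_table(n_positions: int, dmodel: int) -> PositionalEncoding:
    if dmodel % 2 != 0:
        raise ValueError("dmodel must be even")
    if n_positions < 1:
        raise ValueError("n_positions must be >= 1")
    pos = np.arange(n_positions)[:, None].astype(float)
    a = np.arange(dmodel // 2)[None, :].astype(float)
    angle = pos / np.power(10000.0, 2.0 * a / dmodel)
    table = np.zeros((n_positions, dmodel))
    table[:, 0::2] = np.sin(angle)
    table[:, 1::2] = np.cos(angle)
    return PositionalEncoding(n_positions, dmodel, table)


def embed_tokens(enc: KmerEncoding, embedding: Tensor, pe: PositionalEncoding) -> Tensor:
    """Starred encoding matrix: token embedding plus positional table.

    Returns an (entities x positions x dmodel) tensor
    ``out[e, p, :] = embedding[token_ids[e, p], :] + pe.table[p, :]``.
    """
    if not isinstance(embedding, Tensor):
        embedding = Tensor(np.asarray(embedding))
    n_pos = enc.token_ids.shape[1]
    if pe.n_positions < n_pos:
        raise ValueError("positional table shorter than the token matrix")
    if pe.dmodel != embedding.shape[1]:
        raise ValueError("positional table width != embedding width")
    emb = embedding.take(enc.token_ids, axis=0)  # (E, P, d)
    return emb + Tensor(pe.table[:n_pos].astype(embedding.dtype))
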