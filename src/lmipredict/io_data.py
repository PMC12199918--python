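"""Reading, writing and splitting of lncRNA/miRNA interaction datasets.

Sequences travel as FASTA (T normalized to U on input), expression profiles
as TSV matrices (entities x conditions), and interactions as TSV edge lists
with columns ``lnc_id``, ``mir_id``, ``label``.  Cross-validation plans come
in three flavours: ``hot`` (stratified pair-level folds) and the two
entity-exclusion cold-start protocols ``cold_lnc`` / ``cold_mir``, in which
the centred entity class is partitioned so that validation entities have no
interactions visible during training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from sklearn.model_selection import StratifiedKFold

RNA_ALPHABET = frozenset("ACGU")
RNA_CLASSES = ("lncRNA", "miRNA")
SPLIT_MODES = ("hot", "cold_lnc", "cold_mir")


class FormatError(ValueError):
    """Malformed input file or record."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    rna_class: str
    sequence: str

    def __post_init__(self):
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown rna_class {self.rna_class!r}")
        if not self.sequence:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)} after T->U normalization"
            )


@dataclass(frozen=True)
class ExpressionProfile:
    id: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise FormatError(f"profile {self.id!r}: need >= 2 conditions, got {v.size}")
        if not np.all(np.isfinite(v)):
            raise FormatError(f"profile {self.id!r}: non-finite values")


@dataclass
class InteractionSet:
    """Labelled lncRNA-miRNA pairs over fixed entity orderings."""

    lnc_ids: list
    mir_ids: list
    pairs: list  # (lnc_id, mir_id, label)

    def __post_init__(self):
        if len(set(self.lnc_ids)) != len(self.lnc_ids) or len(set(self.mir_ids)) != len(self.mir_ids):
            raise FormatError("duplicate entity ids")
        self._lidx = {x: i for i, x in enumerate(self.lnc_ids)}
        self._midx = {x: i for i, x in enumerate(self.mir_ids)}
        seen = set()
        for l, m, lab in self.pairs:
            if l not in self._lidx or m not in self._midx:
                raise FormatError(f"pair ({l}, {m}) references unknown entity")
            if (l, m) in seen:
                raise FormatError(f"duplicate pair ({l}, {m})")
            if lab not in (0, 1):
                raise FormatError(f"pair ({l}, {m}): label must be 0 or 1")
            seen.add((l, m))

    @property
    def labels(self) -> np.ndarray:
        return np.array([lab for _, _, lab in self.pairs], dtype=int)

    @property
    def pair_indices(self) -> np.ndarray:
        """(n_pairs, 2) integer array of (lnc index, mir index)."""
        return np.array(
            [[self._lidx[l], self._midx[m]] for l, m, _ in self.pairs], dtype=int
        ).reshape(-1, 2)

    def adjacency(self, pair_subset=None) -> np.ndarray:
        """Binary n_lnc x n_mir matrix from label-1 pairs (optionally a subset)."""
        A = np.zeros((len(self.lnc_ids), len(self.mir_ids)), dtype=float)
        idx = range(len(self.pairs)) if pair_subset is None else pair_subset
        for i in idx:
            l, m, lab = self.pairs[i]
            if lab == 1:
                A[self._lidx[l], self._midx[m]] = 1.0
        return A


@dataclass
class SplitPlan:
    folds: list  # [(train_idx ndarray, val_idx ndarray), ...]
    mode: str
    seed: int

    def __post_init__(self):
        if self.mode not in SPLIT_MODES:
            raise ValueError(f"unknown split mode {self.mode!r}")


# ---------------------------------------------------------------------- FASTA
def read_fasta(path, rna_class: str) -> list:
    """Parse a FASTA file into SequenceRecords, normalizing T/t to U."""
    records, seen = [], set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise FormatError(f"duplicate id {rid!r} in {path}")
        seen.add(rid)
        seq = str(entry.seq).upper().replace("T", "U")
        records.append(SequenceRecord(rid, rna_class, seq))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    return records


def write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.sequence}\n")


# ----------------------------------------------------------------- expression
def read_expression(path) -> list:
    """Parse a TSV expression matrix (first column id, header = conditions)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as e:  # ragged rows
        raise FormatError(f"{path}: {e}") from e
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need >= 2 conditions, got {df.shape[1]}")
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicate entity ids")
    if df.isna().any().any() or not all(np.issubdtype(d, np.number) for d in df.dtypes):
        raise FormatError(f"{path}: non-numeric or missing cells")
    return [ExpressionProfile(str(i), row.to_numpy(dtype=float)) for i, row in df.iterrows()]


def write_expression(path, profiles) -> None:
    df = pd.DataFrame(
        np.vstack([p.values for p in profiles]),
        index=[p.id for p in profiles],
        columns=[f"cond{j}" for j in range(len(profiles[0].values))],
    )
    df.to_csv(path, sep="\t", index_label="id")


# ---------------------------------------------------------------- interactions
def read_interactions(path, lnc_ids=None, mir_ids=None) -> InteractionSet:
    df = pd.read_csv(path, sep="\t", dtype={"lnc_id": str, "mir_id": str})
    for col in ("lnc_id", "mir_id", "label"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    pairs = list(zip(df["lnc_id"], df["mir_id"], df["label"].astype(int)))
    if lnc_ids is None:
        lnc_ids = list(dict.fromkeys(df["lnc_id"]))
    if mir_ids is None:
        mir_ids = list(dict.fromkeys(df["mir_id"]))
    return InteractionSet(list(lnc_ids), list(mir_ids), pairs)


def write_interactions(path, data: InteractionSet) -> None:
    pd.DataFrame(data.pairs, columns=["lnc_id", "mir_id", "label"]).to_csv(
        path, sep="\t", index=False
    )


# ------------------------------------------------------------------- sampling
def sample_negatives(positives: InteractionSet, ratio: int, seed: int) -> InteractionSet:
    """Add ratio x |positives| uniformly sampled unobserved pairs as negatives."""
    if ratio < 1:
        raise ValueError("ratio must be a positive integer")
    n_l, n_m = len(positives.lnc_ids), len(positives.mir_ids)
    pos = [(l, m) for l, m, lab in positives.pairs if lab == 1]
    n_pos = len(pos)
    observed = set((l, m) for l, m, _ in positives.pairs)
    free = [
        (l, m)
        for l in positives.lnc_ids
        for m in positives.mir_ids
        if (l, m) not in observed
    ]
    need = ratio * n_pos
    if need > len(free):
        max_ratio = len(free) // n_pos if n_pos else 0
        raise ValueError(
            f"cannot sample {need} negatives from {len(free)} unobserved cells "
            f"(maximum feasible ratio: {max_ratio})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(free), size=need, replace=False)
    negatives = [(free[i][0], free[i][1], 0) for i in sorted(chosen)]
    return InteractionSet(
        list(positives.lnc_ids), list(positives.mir_ids), list(positives.pairs) + negatives
    )


# ---------------------------------------------------------------------- folds
def make_folds(data: InteractionSet, k: int, mode: str, seed: int) -> SplitPlan:
    """Build a k-fold cross-validation plan (hot or entity-exclusion cold)."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if mode not in SPLIT_MODES:
        raise ValueError(f"unknown split mode {mode!r}")
    n = len(data.pairs)
    if mode == "hot":
        if k > n:
            raise ValueError(f"k={k} exceeds pair count {n}")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [
            (np.asarray(tr), np.asarray(va))
            for tr, va in skf.split(np.zeros(n), data.labels)
        ]
        return SplitPlan(folds, mode, seed)

    ids = data.lnc_ids if mode == "cold_lnc" else data.mir_ids
    col = 0 if mode == "cold_lnc" else 1
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} entities of the centred class")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    groups = np.array_split(perm, k)
    ent = data.pair_indices[:, col]
    folds = []
    for g in groups:
        held = np.isin(ent, g)
        folds.append((np.flatnonzero(~held), np.flatnonzero(held)))
    return SplitPlan(folds, mode, seed)


def check_cold_start(plan: SplitPlan, data: InteractionSet, mode: str | None = None) -> bool:
    """True iff no centred-class entity appears in both train and validation pairs.

    The centred class defaults to the plan's own mode; pass ``mode`` explicitly
    to audit a plan against a different protocol (e.g. a hot plan under the
    ``cold_lnc`` criterion).  A hot criterion imposes no exclusion and is
    vacuously satisfied.
    """
    mode = plan.mode if mode is None else mode
    if mode == "hot":
        return True
    col = 0 if mode == "cold_lnc" else 1
    idx = data.pair_indices
    for tr, va in plan.folds:
        if set(idx[tr, col]) & set(idx[va, col]):
            return False
    return True
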