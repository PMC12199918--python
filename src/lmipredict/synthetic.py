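"""Synthetic lncRNA/miRNA corpora with planted multimodal interaction signal.

The generator emulates the statistical structure the predictor assumes:

* two entity sets with realistic length disparity (lncRNAs ~hundreds of nt,
  miRNAs ~22 nt);
* a sparse bipartite interaction matrix whose positives carry sequence
  signal: each miRNA has a seed region (positions 2..2+motif_len-1, 1-based)
  and, for every interacting pair, the reverse complement (A<->U, C<->G) of
  that seed is implanted at a random position of the lncRNA with per-base
  substitution at rate ``noise`` — mimicking seed-site complementarity;
* expression profiles whose pairwise Pearson correlation is elevated for
  interacting pairs with expectation ~ ``expr_rho``.

Interactions are planted with co-regulation module (community) structure:
lncRNAs and miRNAs are partitioned into matched modules, positives are drawn
within module blocks, and each module shares a latent expression factor.  A
module structure is the only way an entity of degree d can be strongly
correlated with all d of its partners (with mutually independent partner
factors the squared correlations would have to sum to at most one), and it
mirrors the co-expression of genuinely co-regulated RNA modules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_data import ExpressionProfile, InteractionSet, SequenceRecord, write_expression, write_fasta, write_interactions

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
BASES = "ACGU"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    n_lnc: int = 80
    n_mir: int = 40
    lnc_len: int = 400
    mir_len: int = 22
    n_conditions: int = 50
    density: float = 0.1
    motif_len: int = 7
    expr_rho: float = 0.8
    noise: float = 0.0
    n_modules: int = 8
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.density < 1:
            raise ValueError("density must be in (0, 1)")
        if self.motif_len > self.mir_len - 1:
            raise ValueError("motif must fit in the miRNA after position 2")
        if self.motif_len > self.lnc_len:
            raise ValueError("motif longer than the lncRNA")
        if not 0 <= self.expr_rho <= 1:
            raise ValueError("expr_rho must be in [0, 1]")
        if not 0 <= self.noise <= 1:
            raise ValueError("noise must be in [0, 1]")
        if self.n_conditions < 2:
            raise ValueError("need >= 2 expression conditions")
        if self.n_modules > min(self.n_lnc, self.n_mir):
            raise ValueError("more modules than entities")


@dataclass
class SyntheticDataset:
    cfg: SimConfig
    lnc_records: list
    mir_records: list
    lnc_profiles: list
    mir_profiles: list
    interactions: InteractionSet  # ground-truth positives only

    def write(self, outdir):
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "lnc.fasta", self.lnc_records)
        write_fasta(outdir / "mir.fasta", self.mir_records)
        write_expression(outdir / "lnc_expression.tsv", self.lnc_profiles)
        write_expression(outdir / "mir_expression.tsv", self.mir_profiles)
        write_interactions(outdir / "interactions.tsv", self.interactions)


def _random_seq(rng, length):
    return "".join(rng.choice(list(BASES), size=length))


def _free_start(rng, used, length, motif_len, max_tries=200):
    """Random implant start that does not overlap earlier implants, so every
    interacting partner keeps its own intact binding site."""
    for _ in range(max_tries):
        s = int(rng.integers(0, length - motif_len + 1))
        if all(s + motif_len <= a or s >= b for a, b in used):
            return s
    raise ValueError(
        f"cannot place {len(used) + 1} disjoint length-{motif_len} sites in a "
        f"length-{length} sequence; increase lnc_len or lower density"
    )


def _mutate(rng, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = BASES[rng.integers(4)]
    return "".join(out)


def generate(cfg: SimConfig) -> SyntheticDataset:
    """Generate a fully reproducible corpus with planted bimodal signal."""
    rng = np.random.default_rng(cfg.seed)
    lnc_ids = [f"lnc{i:04d}" for i in range(cfg.n_lnc)]
    mir_ids = [f"mir{i:04d}" for i in range(cfg.n_mir)]

    # module assignment: contiguous, near-equal blocks
    lnc_mod = np.array_split(np.arange(cfg.n_lnc), cfg.n_modules)
    mir_mod = np.array_split(np.arange(cfg.n_mir), cfg.n_modules)
    module_of_lnc = np.empty(cfg.n_lnc, dtype=int)
    module_of_mir = np.empty(cfg.n_mir, dtype=int)
    for m, (li, mi) in enumerate(zip(lnc_mod, mir_mod)):
        module_of_lnc[li] = m
        module_of_mir[mi] = m

    # positives: uniform over within-module block cells
    block_cells = [
        (i, j) for i in range(cfg.n_lnc) for j in range(cfg.n_mir)
        if module_of_lnc[i] == module_of_mir[j]
    ]
    n_pos = int(np.floor(cfg.density * cfg.n_lnc * cfg.n_mir))
    if n_pos < 1 or n_pos > len(block_cells):
        raise ValueError(
            f"density {cfg.density} infeasible: {n_pos} positives requested, "
            f"{len(block_cells)} within-module cells available"
        )
    chosen = rng.choice(len(block_cells), size=n_pos, replace=False)
    positives = sorted(block_cells[c] for c in chosen)

    # sequences: miRNAs with designated seed regions, lncRNAs with implants
    mir_seqs = [_random_seq(rng, cfg.mir_len) for _ in range(cfg.n_mir)]
    seeds = [s[1:1 + cfg.motif_len] for s in mir_seqs]  # positions 2..2+motif_len-1
    lnc_seqs = [list(_random_seq(rng, cfg.lnc_len)) for _ in range(cfg.n_lnc)]
    occupied = [[] for _ in range(cfg.n_lnc)]  # implant intervals, kept disjoint
    for i, j in positives:
        site = reverse_complement(seeds[j])
        site = _mutate(rng, site, cfg.noise)
        start = _free_start(rng, occupied[i], cfg.lnc_len, cfg.motif_len)
        occupied[i].append((start, start + cfg.motif_len))
        lnc_seqs[i][start:start + cfg.motif_len] = list(site)

    lnc_records = [
        SequenceRecord(lnc_ids[i], "lncRNA", "".join(lnc_seqs[i])) for i in range(cfg.n_lnc)
    ]
    mir_records = [SequenceRecord(mir_ids[j], "miRNA", mir_seqs[j]) for j in range(cfg.n_mir)]

    # expression: per-module latent factor mixed at sqrt(rho)
    C = cfg.n_conditions
    factors = rng.standard_normal((cfg.n_modules, C))
    w = np.sqrt(cfg.expr_rho)
    lnc_expr = w * factors[module_of_lnc] + np.sqrt(1 - cfg.expr_rho) * rng.standard_normal((cfg.n_lnc, C))
    mir_expr = w * factors[module_of_mir] + np.sqrt(1 - cfg.expr_rho) * rng.standard_normal((cfg.n_mir, C))
    lnc_profiles = [ExpressionProfile(lnc_ids[i], lnc_expr[i]) for i in range(cfg.n_lnc)]
    mir_profiles = [ExpressionProfile(mir_ids[j], mir_expr[j]) for j in range(cfg.n_mir)]

    interactions = InteractionSet(
        lnc_ids, mir_ids, [(lnc_ids[i], mir_ids[j], 1) for i, j in positives]
    )
    return SyntheticDataset(cfg, lnc_records, mir_records, lnc_profiles, mir_profiles, interactions)


def _pair_seq_affinity(lnc_seq: str, seed: str) -> float:
    """Best seed-site complementarity: 1 - (best infix edit distance)/|seed|."""
    import edlib

    site = reverse_complement(seed)
    d = edlib.align(site, lnc_seq, mode="HW", task="distance")["editDistance"]
    return 1.0 - d / len(site)


def difficulty_report(dataset: SyntheticDataset, max_pairs: int = 2000, seed: int = 0) -> dict:
    """Separability proxies: positive-vs-negative gaps in both modalities.

    Sequence affinity is the best match of each miRNA's reverse-complemented
    seed inside the lncRNA; expression affinity is the pairwise Pearson
    correlation.  Gaps are (mean over positives) - (mean over sampled
    negatives).
    """
    cfg = dataset.cfg
    rng = np.random.default_rng(seed)
    pos = {(l, m) for l, m, lab in dataset.interactions.pairs if lab == 1}
    lidx = {r.id: i for i, r in enumerate(dataset.lnc_records)}
    midx = {r.id: j for j, r in enumerate(dataset.mir_records)}
    all_neg = [
        (l.id, m.id) for l in dataset.lnc_records for m in dataset.mir_records
        if (l.id, m.id) not in pos
    ]
    take = min(len(all_neg), max(len(pos), 1), max_pairs)
    neg = [all_neg[i] for i in rng.choice(len(all_neg), size=take, replace=False)]

    lnc_seq = [r.sequence for r in dataset.lnc_records]
    mir_seq = [r.sequence for r in dataset.mir_records]
    seeds = [s[1:1 + cfg.motif_len] for s in mir_seq]
    lnc_X = np.vstack([p.values for p in dataset.lnc_profiles])
    mir_X = np.vstack([p.values for p in dataset.mir_profiles])

    def seq_aff(pairs):
        return np.mean([_pair_seq_affinity(lnc_seq[lidx[l]], seeds[midx[m]]) for l, m in pairs])

    def expr_corr(pairs):
        return np.mean(
            [np.corrcoef(lnc_X[lidx[l]], mir_X[midx[m]])[0, 1] for l, m in pairs]
        )

    pos_list = sorted(pos)
    report = {
        "n_lnc": cfg.n_lnc,
        "n_mir": cfg.n_mir,
        "n_positives": len(pos),
        "density": len(pos) / (cfg.n_lnc * cfg.n_mir),
        "mean_seq_affinity_pos": float(seq_aff(pos_list)),
        "mean_seq_affinity_neg": float(seq_aff(neg)),
        "mean_expr_corr_pos": float(expr_corr(pos_list)),
        "mean_expr_corr_neg": float(expr_corr(neg)),
    }
    report["seq_affinity_gap"] = report["mean_seq_affinity_pos"] - report["mean_seq_affinity_neg"]
    report["expr_corr_gap"] = report["mean_expr_corr_pos"] - report["mean_expr_corr_neg"]
    return report
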