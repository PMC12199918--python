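import numpy as np
import pytest

from lmipredict.io_data import ExpressionProfile, InteractionSet, SequenceRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_records(rng, n, length, rna_class, prefix):
    bases = np.array(list("ACGU"))
    return [
        SequenceRecord(f"{prefix}{i}", rna_class, "".join(rng.choice(bases, size=length)))
        for i in range(n)
    ]


@pytest.fixture
def lnc_records(rng):
    return make_records(rng, 6, 40, "lncRNA", "l")


@pytest.fixture
def mir_records(rng):
    return make_records(rng, 4, 22, "miRNA", "m")


@pytest.fixture
def small_interactions():
    lnc = [f"l{i}" for i in range(4)]
    mir = [f"m{j}" for j in range(3)]
    pairs = [("l0", "m0", 1), ("l0", "m1", 1), ("l1", "m1", 1), ("l2", "m2", 1), ("l3", "m0", 1)]
    return InteractionSet(lnc, mir, pairs)


def profiles_from(rng, ids, n_cond=8):
    return [ExpressionProfile(i, rng.standard_normal(n_cond)) for i in ids]
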