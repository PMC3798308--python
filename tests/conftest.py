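import numpy as np
import pandas as pd
import pytest

from haplopop.io_core import (
    HaplotypePartition,
    LocusAlignment,
    PairwiseDifferenceMatrix,
)


def make_alignment(seqs, pops=None, locus="test"):
    """LocusAlignment from a list of sequences (s0, s1, ... sample ids)."""
    ids = [f"s{i}" for i in range(len(seqs))]
    if pops is None:
        pops = ["pop1"] * len(seqs)
    return LocusAlignment.from_sequences(
        locus, ids, seqs, dict(zip(ids, pops))
    )


def make_partition(counts_by_pop, d):
    """HaplotypePartition + PairwiseDifferenceMatrix from a counts dict
    {pop: [count per haplotype]} and a difference matrix."""
    pops = list(counts_by_pop)
    k = len(counts_by_pop[pops[0]])
    counts = pd.DataFrame(
        [counts_by_pop[p] for p in pops],
        index=pops,
        columns=[f"hap{i}" for i in range(k)],
    )
    assignment = {}
    i = 0
    for p in pops:
        for h, c in enumerate(counts_by_pop[p]):
            for _ in range(c):
                assignment[f"s{i}"] = h
                i += 1
    hp = HaplotypePartition(
        haplotypes=[f"<{i}>" for i in range(k)],
        assignment=assignment,
        counts=counts,
        retained_sites=np.arange(int(np.max(d)) + 1),
    )
    dm = PairwiseDifferenceMatrix(
        d=np.asarray(d), L_effective=int(np.max(d)) + 1
    )
    return hp, dm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_alignment(rng):
    """20 x 50 random low-diversity alignment over two populations."""
    base = rng.choice(list("ACGT"), size=50)
    seqs = []
    for _ in range(20):
        row = base.copy()
        nmut = rng.poisson(1.5)
        for site in rng.choice(50, size=min(nmut, 50), replace=False):
            row[site] = rng.choice([b for b in "ACGT" if b != row[site]])
        seqs.append("".join(row))
    pops = ["pop1"] * 10 + ["pop2"] * 10
    return make_alignment(seqs, pops)
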