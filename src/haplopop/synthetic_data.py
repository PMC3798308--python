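"""Coalescent-based generators for haplotype datasets and test fixtures.

Three scenarios cover the regimes the analyses distinguish:

* ``panmictic_equilibrium`` — the standard neutral Kingman coalescent
  (exponential coalescence times at rate C(j,2), mutations Poisson at rate
  theta/2 per lineage per unit of coalescent time, infinite-sites mutations
  mapped onto distinct sites of an L-site sequence);
* ``star_expansion`` — a star genealogy in which every lineage accumulates
  Poisson(tau/2) private mutations, the limiting genealogy of an extreme
  sudden expansion (pairwise differences ~ Poisson(tau));
* ``island_structured`` — a finite-island structured coalescent with
  scaled migration rate M = 2*N*m per lineage, producing a target
  F_ST ~ 1 / (1 + 2*N*m*(d/(d-1))^2) for d demes (haploid scaling).

A sudden-expansion coalescent (instantaneous size change at mutational
time tau/theta1) backs the mismatch-distribution bootstrap.

All generators are deterministic given a seed and emit alignments that
round-trip losslessly through the FASTA/popmap readers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from haplopop.io_core import LocusAlignment

_BASES = np.array(list("ACGT"))


@dataclass
class SimulatedSample:
    """Sequences plus sample/population labels produced by a generator."""

    sample_ids: list[str]
    sequences: list[str]
    population_of: dict[str, str]
    locus_name: str = "sim"

    def to_alignment(self) -> LocusAlignment:
        return LocusAlignment.from_sequences(
            self.locus_name, self.sample_ids, self.sequences, self.population_of
        )


@dataclass
class GeneratorSpec:
    """Declarative description of a synthetic dataset."""

    scenario: str  # panmictic_equilibrium | star_expansion | island_structured
    n_populations: int = 1
    samples_per_population: int = 20
    L: int = 379
    theta: float = 1.0
    tau: float = 0.5
    migration_rate: float = 1.0  # M = 2*N*m, per lineage
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 1 or self.samples_per_population < 1:
            raise ValueError("population counts must be positive")
        if self.L < 1:
            raise ValueError("L must be >= 1")
        if self.scenario not in (
            "panmictic_equilibrium",
            "star_expansion",
            "island_structured",
        ):
            raise ValueError(f"unknown scenario {self.scenario!r}")


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _coalescent_mutation_sets(
    n: int, theta: float, rng: np.random.Generator
) -> list[list[int]]:
    """Neutral Kingman genealogy; returns, per sample, the list of mutation
    ids it carries (infinite-sites; each id is a unique mutation).

    Mutations fall on each active lineage as Poisson(theta/2 * dt).
    """
    lineages: list[list[int]] = [[i] for i in range(n)]  # leaves below
    muts: list[list[int]] = [[] for _ in range(n)]
    next_mut = 0
    j = n
    while j > 1:
        t = rng.exponential(1.0 / (j * (j - 1) / 2.0))
        if theta > 0:
            for lin in lineages:
                m = rng.poisson(theta / 2.0 * t)
                for _ in range(m):
                    for leaf in lin:
                        muts[leaf].append(next_mut)
                    next_mut += 1
        a, b = rng.choice(j, size=2, replace=False)
        a, b = (int(a), int(b)) if a < b else (int(b), int(a))
        lineages[a] = lineages[a] + lineages[b]
        lineages.pop(b)
        j -= 1
    return muts


def _mutation_carrier_counts(muts: list[list[int]]) -> np.ndarray:
    counts: dict[int, int] = {}
    for mset in muts:
        for m in mset:
            counts[m] = counts.get(m, 0) + 1
    return np.array(list(counts.values()), dtype=float)


def summaries_from_mutation_sets(muts: list[list[int]]) -> tuple[int, float, int]:
    """(S, mean pairwise differences, haplotype count) for one sample."""
    n = len(muts)
    carriers = _mutation_carrier_counts(muts)
    S = carriers.size
    pi_hat = (
        float(np.sum(carriers * (n - carriers))) / (n * (n - 1) / 2.0)
        if S
        else 0.0
    )
    k = len({frozenset(m) for m in muts})
    return S, pi_hat, k


def coalescent_summaries(
    n: int, theta: float, rng
) -> tuple[int, float, int]:
    """Fast path: (S, pi_hat, k) of one neutral coalescent sample."""
    return summaries_from_mutation_sets(
        _coalescent_mutation_sets(n, theta, _as_rng(rng))
    )


def _sequences_from_mutation_sets(
    muts: list[list[int]], L: int, rng: np.random.Generator
) -> list[str]:
    """Map infinite-sites mutations onto distinct sites of an L-site locus."""
    all_muts = sorted({m for mset in muts for m in mset})
    S = len(all_muts)
    if S > L:
        raise ValueError(
            f"{S} mutations cannot occupy distinct sites of an L={L} locus"
        )
    ancestral = rng.choice(_BASES, size=L)
    sites = rng.choice(L, size=S, replace=False)
    derived = {}
    for m, s in zip(all_muts, sites):
        alternatives = [b for b in "ACGT" if b != ancestral[s]]
        derived[m] = (int(s), alternatives[rng.integers(3)])
    seqs = []
    for mset in muts:
        row = ancestral.copy()
        for m in mset:
            s, b = derived[m]
            row[s] = b
        seqs.append("".join(row))
    return seqs


def simulate_neutral_coalescent(
    n: int, theta: float, L: int = 379, seed=0, locus_name: str = "neutral"
) -> SimulatedSample:
    """Panmictic neutral sample of n sequences at an L-site locus."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    rng = _as_rng(seed)
    muts = _coalescent_mutation_sets(n, theta, rng)
    seqs = _sequences_from_mutation_sets(muts, L, rng)
    ids = [f"s{i:03d}" for i in range(n)]
    return SimulatedSample(ids, seqs, {i: "pop1" for i in ids}, locus_name)


def star_mutation_sets(
    n: int, tau: float, rng: np.random.Generator
) -> list[list[int]]:
    """Star genealogy: every lineage carries Poisson(tau/2) private
    mutations, so pairwise differences are ~ Poisson(tau)."""
    muts: list[list[int]] = []
    next_mut = 0
    for _ in range(n):
        m = rng.poisson(tau / 2.0)
        muts.append(list(range(next_mut, next_mut + m)))
        next_mut += m
    return muts


def simulate_star_expansion(
    n: int, tau: float, L: int = 379, seed=0, locus_name: str = "star"
) -> SimulatedSample:
    """Extreme sudden-expansion sample (star genealogy)."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    rng = _as_rng(seed)
    muts = star_mutation_sets(n, tau, rng)
    seqs = _sequences_from_mutation_sets(muts, L, rng)
    ids = [f"s{i:03d}" for i in range(n)]
    return SimulatedSample(ids, seqs, {i: "pop1" for i in ids}, locus_name)


def sudden_expansion_mutation_sets(
    n: int,
    tau: float,
    theta0: float,
    theta1: float,
    rng: np.random.Generator,
) -> list[list[int]]:
    """Coalescent with an instantaneous size change.

    Time runs in units of 2*N1 generations; mutations fall at rate theta1/2
    per lineage. Older than t_change = tau/theta1 the coalescence rate is
    multiplied by theta1/theta0 (theta0 = 0 collapses every remaining
    lineage at the change point — the star limit).
    """
    if math.isinf(theta1):
        theta1 = 1e4  # effectively instantaneous growth from theta0
    if theta1 <= 0:
        raise ValueError("theta1 must be > 0")
    t_change = tau / theta1
    lineages: list[list[int]] = [[i] for i in range(n)]
    muts: list[list[int]] = [[] for _ in range(n)]
    next_mut = 0

    def drop_mutations(dt: float) -> None:
        nonlocal next_mut
        if theta1 <= 0 or dt <= 0:
            return
        for lin in lineages:
            m = rng.poisson(theta1 / 2.0 * dt)
            for _ in range(m):
                for leaf in lin:
                    muts[leaf].append(next_mut)
                next_mut += 1

    t = 0.0
    epoch_new = True
    while len(lineages) > 1:
        j = len(lineages)
        rate = j * (j - 1) / 2.0
        if not epoch_new:
            if theta0 == 0:
                # collapse everything at the change point
                w = 0.0
            else:
                rate *= theta1 / theta0
                w = rng.exponential(1.0 / rate)
        else:
            w = rng.exponential(1.0 / rate)
        if epoch_new and t + w > t_change:
            drop_mutations(t_change - t)
            t = t_change
            epoch_new = False
            continue
        drop_mutations(w)
        t += w
        a, b = rng.choice(j, size=2, replace=False)
        a, b = (int(a), int(b)) if a < b else (int(b), int(a))
        lineages[a] = lineages[a] + lineages[b]
        lineages.pop(b)
    return muts


def simulate_sudden_expansion_pairs(
    n: int, tau: float, theta0: float, theta1: float, rng
) -> np.ndarray:
    """Mismatch frequency vector of one sudden-expansion coalescent sample."""
    muts = sudden_expansion_mutation_sets(n, tau, theta0, theta1, _as_rng(rng))
    sets = [frozenset(m) for m in muts]
    dmax = 0
    diffs = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            dij = len(sets[i] ^ sets[j])
            diffs[i, j] = dij
            dmax = max(dmax, dij)
    freqs = np.zeros(dmax + 1)
    iu = np.triu_indices(n, k=1)
    np.add.at(freqs, diffs[iu], 1.0)
    return freqs / iu[0].size


def simulate_island_model(spec: GeneratorSpec) -> SimulatedSample:
    """Finite-island structured coalescent sample.

    Within-deme pairs coalesce at rate 1 per pair (time in units of 2N per
    deme); every lineage migrates at rate M/2 = N*m to a uniformly chosen
    other deme. Mutations fall at rate theta/2 per lineage.
    """
    if spec.scenario != "island_structured":
        raise ValueError("spec.scenario must be 'island_structured'")
    rng = _as_rng(spec.seed)
    P = spec.n_populations
    n_per = spec.samples_per_population
    n = P * n_per
    deme = [i // n_per for i in range(n)]
    lineages = [[i] for i in range(n)]
    lin_deme = list(deme)
    muts: list[list[int]] = [[] for _ in range(n)]
    next_mut = 0
    while len(lineages) > 1:
        counts = np.bincount(lin_deme, minlength=P)
        coal_rates = counts * (counts - 1) / 2.0
        mig_rate = spec.migration_rate / 2.0 * len(lineages) if P > 1 else 0.0
        total = float(coal_rates.sum() + mig_rate)
        if total == 0:
            raise RuntimeError("structured coalescent stalled")
        w = rng.exponential(1.0 / total)
        if spec.theta > 0:
            for li, lin in enumerate(lineages):
                m = rng.poisson(spec.theta / 2.0 * w)
                for _ in range(m):
                    for leaf in lin:
                        muts[leaf].append(next_mut)
                    next_mut += 1
        if rng.uniform() < coal_rates.sum() / total:
            # coalescence in a deme chosen proportionally to its pair count
            dsel = rng.choice(P, p=coal_rates / coal_rates.sum())
            idx = [i for i, dd in enumerate(lin_deme) if dd == dsel]
            a, b = rng.choice(len(idx), size=2, replace=False)
            ia, ib = idx[int(a)], idx[int(b)]
            ia, ib = (ia, ib) if ia < ib else (ib, ia)
            lineages[ia] = lineages[ia] + lineages[ib]
            lineages.pop(ib)
            lin_deme.pop(ib)
        else:
            li = int(rng.integers(len(lineages)))
            others = [d for d in range(P) if d != lin_deme[li]]
            lin_deme[li] = int(others[rng.integers(len(others))])
    seqs = _sequences_from_mutation_sets(muts, spec.L, rng)
    ids = [f"s{i:03d}" for i in range(n)]
    return SimulatedSample(
        ids,
        seqs,
        {f"s{i:03d}": f"pop{deme[i] + 1}" for i in range(n)},
        "island",
    )


def generate(spec: GeneratorSpec) -> SimulatedSample:
    """Dispatch on the scenario of a GeneratorSpec."""
    if spec.scenario == "panmictic_equilibrium":
        n = spec.n_populations * spec.samples_per_population
        sample = simulate_neutral_coalescent(n, spec.theta, spec.L, spec.seed)
    elif spec.scenario == "star_expansion":
        n = spec.n_populations * spec.samples_per_population
        sample = simulate_star_expansion(n, spec.tau, spec.L, spec.seed)
    else:
        return simulate_island_model(spec)
    if spec.n_populations > 1:
        # panmictic/star samples split evenly into arbitrary sampling sites
        pop_of = {
            sid: f"pop{i // spec.samples_per_population + 1}"
            for i, sid in enumerate(sample.sample_ids)
        }
        sample = SimulatedSample(
            sample.sample_ids, sample.sequences, pop_of, sample.locus_name
        )
    return sample


def polycystum_like(seed: int = 0) -> GeneratorSpec:
    """Preset emulating a low-diversity, recently expanded macroalga dataset:
    many sampling sites, few haplotypes, a handful of polymorphic sites over
    a 379-bp organellar locus."""
    return GeneratorSpec(
        scenario="star_expansion",
        n_populations=27,
        samples_per_population=7,
        L=379,
        tau=0.06,  # E[S] = n*tau/2 ~ 5.7 for 189 sequences: the observed regime
        seed=seed,
    )


def write_fixture(
    sample: SimulatedSample, fasta_path: str | Path, popmap_path: str | Path
) -> None:
    """Write a sample as FASTA + popmap TSV (round-trips through read_locus)."""
    with open(fasta_path, "w") as fh:
        for sid, seq in zip(sample.sample_ids, sample.sequences):
            fh.write(f">{sid}\n{seq}\n")
    with open(popmap_path, "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for sid in sample.sample_ids:
            fh.write(f"{sid}\t{sample.population_of[sid]}\n")
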