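"""Alignment input, haplotype collapsing and pairwise difference matrices.

Alignments are equal-length nucleotide matrices (one row per sample) with a
sample -> population map. Every downstream statistic (diversity indices,
neutrality tests, AMOVA, mismatch distributions, networks) is computed from
the haplotype partition and the haplotype-by-haplotype difference matrix
produced here.

Site handling: ambiguity codes other than N are collapsed to N; under the
default ``complete_deletion`` policy any column containing '-' or 'N' in any
sequence is removed before haplotypes are compared, so that all statistics
share one common site set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGT")
GAP_OR_MISSING = frozenset("-N")
# IUPAC ambiguity symbols accepted on input; anything not A/C/G/T/- becomes N.
IUPAC = frozenset("ACGTURYSWKMBDHVN-")


class AlignmentError(ValueError):
    """Raised for malformed alignments (unequal lengths, bad symbols)."""


class MetadataError(ValueError):
    """Raised when sample metadata and the alignment disagree."""


class DegenerateInputError(ValueError):
    """Raised when an operation has no sites or samples left to work on."""


@dataclass
class LocusAlignment:
    """Equal-length nucleotide alignment for one locus.

    ``matrix`` holds uppercase single characters, shape (n_samples, L).
    """

    locus_name: str
    sample_ids: list[str]
    matrix: np.ndarray
    population_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2:
            raise AlignmentError("sequence matrix must be 2-D")
        if self.matrix.shape[0] != len(self.sample_ids):
            raise AlignmentError("one row per sample required")
        if self.matrix.shape[1] < 1:
            raise AlignmentError("alignment length must be >= 1")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = {s for s in self.sample_ids if self.sample_ids.count(s) > 1}
            raise MetadataError(f"duplicate sample ids: {sorted(dupes)}")
        missing = [s for s in self.sample_ids if s not in self.population_of]
        if missing:
            raise MetadataError(f"samples without population label: {missing}")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def L(self) -> int:
        return int(self.matrix.shape[1])

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: list[str] = []
        for s in self.sample_ids:
            p = self.population_of[s]
            if p not in seen:
                seen.append(p)
        return seen

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for s in self.sample_ids:
            p = self.population_of[s]
            sizes[p] = sizes.get(p, 0) + 1
        return sizes

    @classmethod
    def from_sequences(
        cls,
        locus_name: str,
        sample_ids: list[str],
        sequences: list[str],
        population_of: dict[str, str],
    ) -> "LocusAlignment":
        """Build from raw strings; normalizes case and ambiguity codes."""
        if len(sample_ids) != len(sequences):
            raise AlignmentError("sample_ids and sequences length mismatch")
        if not sequences:
            raise AlignmentError("empty alignment")
        L = len(sequences[0])
        rows = []
        for sid, seq in zip(sample_ids, sequences):
            s = seq.upper().replace("U", "T")
            if len(s) != L:
                raise AlignmentError(
                    f"record '{sid}' has length {len(s)}, expected {L}"
                )
            bad = set(s) - IUPAC
            if bad:
                raise AlignmentError(
                    f"record '{sid}' contains invalid symbols {sorted(bad)}"
                )
            # non-N ambiguity codes carry no usable state here
            s = "".join(
                c if (c in VALID_BASES or c == "-") else "N" for c in s
            )
            rows.append(np.frombuffer(s.encode("ascii"), dtype="S1"))
        matrix = np.vstack(rows).astype("U1")
        return cls(locus_name, list(sample_ids), matrix, dict(population_of))


@dataclass
class HaplotypePartition:
    """Distinct haplotypes with per-sample assignment and per-population counts.

    ``haplotypes`` are the retained-site sequences in order of first
    appearance; ``labels`` assigns the conventional H1..Hk names in order of
    decreasing total frequency (ties broken by first appearance).
    """

    haplotypes: list[str]
    assignment: dict[str, int]
    counts: pd.DataFrame  # populations x haplotypes (integer counts)
    retained_sites: np.ndarray  # original 0-based column indices kept
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.labels:
            order = sorted(
                range(len(self.haplotypes)),
                key=lambda i: (-int(self.counts.iloc[:, i].sum()), i),
            )
            rank = {hap_i: r for r, hap_i in enumerate(order)}
            self.labels = [f"H{rank[i] + 1}" for i in range(len(self.haplotypes))]
        total = int(self.counts.to_numpy().sum())
        if total != len(self.assignment):
            raise ValueError("counts do not sum to number of assigned samples")

    @property
    def k(self) -> int:
        return len(self.haplotypes)

    @property
    def n_total(self) -> int:
        return len(self.assignment)

    @property
    def haplotype_counts(self) -> np.ndarray:
        """Total count per haplotype (first-appearance order)."""
        return self.counts.to_numpy().sum(axis=0)

    @property
    def L_retained(self) -> int:
        return int(self.retained_sites.size)

    def to_table(self) -> pd.DataFrame:
        """Haplotype table: label, sequence, per-population counts, total."""
        df = self.counts.T.copy()
        df.insert(0, "sequence", self.haplotypes)
        df.insert(0, "haplotype", self.labels)
        df["total"] = self.haplotype_counts
        return df.reset_index(drop=True)


@dataclass
class PairwiseDifferenceMatrix:
    """Raw site-difference counts between haplotypes over the retained sites."""

    d: np.ndarray
    L_effective: int

    def __post_init__(self) -> None:
        d = np.asarray(self.d)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("difference matrix must be square")
        if not np.array_equal(d, d.T):
            raise ValueError("difference matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("difference matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("differences must be non-negative")
        self.d = d.astype(np.int64)


def read_popmap(popmap_path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a sample->population TSV (columns sample_id, population[, group]).

    Returns (population_of, group_of_population); the latter is empty when no
    group column is present.
    """
    df = pd.read_csv(popmap_path, sep="\t", dtype=str, comment="#")
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    if "sample_id" not in cols or "population" not in cols:
        raise MetadataError(
            "popmap must have columns 'sample_id' and 'population'"
        )
    population_of = dict(zip(df["sample_id"], df["population"]))
    group_of: dict[str, str] = {}
    if "group" in cols:
        for _, row in df.iterrows():
            group_of[row["population"]] = row["group"]
    return population_of, group_of


def read_locus(
    fasta_path: str | Path,
    popmap_path: str | Path,
    locus_name: str | None = None,
) -> LocusAlignment:
    """Read one locus alignment (FASTA) plus its population map (TSV).

    Every FASTA record id must appear in the popmap; sequences must share a
    single length. Case is normalized to upper.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no FASTA records in {fasta_path}")
    population_of, _ = read_popmap(popmap_path)
    sample_ids = [r.id for r in records]
    unknown = [s for s in sample_ids if s not in population_of]
    if unknown:
        raise MetadataError(
            f"FASTA samples missing from popmap: {unknown[:5]}"
            + ("..." if len(unknown) > 5 else "")
        )
    name = locus_name or Path(fasta_path).stem
    return LocusAlignment.from_sequences(
        name,
        sample_ids,
        [str(r.seq) for r in records],
        {s: population_of[s] for s in sample_ids},
    )


def retained_site_mask(matrix: np.ndarray, site_policy: str) -> np.ndarray:
    """Boolean mask of alignment columns kept under the site policy.

    complete_deletion drops every column holding '-' or 'N' in any row;
    pairwise keeps all columns (missing data handled per comparison).
    """
    if site_policy == "complete_deletion":
        bad = np.isin(matrix, ["-", "N"]).any(axis=0)
        return ~bad
    if site_policy == "pairwise":
        return np.ones(matrix.shape[1], dtype=bool)
    raise ValueError(f"unknown site_policy {site_policy!r}")


def collapse_haplotypes(
    aln: LocusAlignment, site_policy: str = "complete_deletion"
) -> HaplotypePartition:
    """Collapse identical sequences (over retained sites) into haplotypes.

    Haplotype order is first appearance; H1..Hk labels rank by total
    frequency. Raises :class:`DegenerateInputError` when no site survives
    the deletion policy.
    """
    mask = retained_site_mask(aln.matrix, site_policy)
    if not mask.any():
        raise DegenerateInputError(
            "no sites retained after applying site policy "
            f"{site_policy!r} (all columns contain gaps or N)"
        )
    sub = aln.matrix[:, mask]
    haplotypes: list[str] = []
    index_of: dict[str, int] = {}
    assignment: dict[str, int] = {}
    for sid, row in zip(aln.sample_ids, sub):
        seq = "".join(row)
        if seq not in index_of:
            index_of[seq] = len(haplotypes)
            haplotypes.append(seq)
        assignment[sid] = index_of[seq]
    pops = aln.populations
    counts = np.zeros((len(pops), len(haplotypes)), dtype=np.int64)
    pop_idx = {p: i for i, p in enumerate(pops)}
    for sid, h in assignment.items():
        counts[pop_idx[aln.population_of[sid]], h] += 1
    counts_df = pd.DataFrame(counts, index=pops,
                             columns=[f"hap{i}" for i in range(len(haplotypes))])
    return HaplotypePartition(
        haplotypes=haplotypes,
        assignment=assignment,
        counts=counts_df,
        retained_sites=np.flatnonzero(mask),
    )


def segregating_sites(
    aln: LocusAlignment, site_policy: str = "complete_deletion"
) -> int:
    """Number of retained columns with >=2 distinct non-gap, non-N states."""
    mask = retained_site_mask(aln.matrix, site_policy)
    sub = aln.matrix[:, mask]
    S = 0
    for col in sub.T:
        states = set(col) - GAP_OR_MISSING
        if len(states) >= 2:
            S += 1
    return S


def pairwise_differences(hp: HaplotypePartition) -> PairwiseDifferenceMatrix:
    """Hamming distances between haplotypes over the retained sites."""
    if hp.k < 1:
        raise DegenerateInputError("need at least one haplotype")
    arr = np.array([list(h) for h in hp.haplotypes])
    k = hp.k
    d = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        diff = (arr[i] != arr).sum(axis=1)
        d[i, :] = diff
    np.fill_diagonal(d, 0)
    return PairwiseDifferenceMatrix(d=d, L_effective=len(hp.haplotypes[0]))


def sample_distance_matrix(
    hp: HaplotypePartition, d: PairwiseDifferenceMatrix, sample_order: list[str]
) -> np.ndarray:
    """Per-individual difference matrix expanded from the haplotype matrix."""
    idx = np.array([hp.assignment[s] for s in sample_order])
    return d.d[np.ix_(idx, idx)]


def write_haplotype_table(hp: HaplotypePartition, path: str | Path) -> None:
    hp.to_table().to_csv(path, sep="\t", index=False)
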