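"""Statistical-parsimony (TCS-style) haplotype networks.

Haplotypes are joined in increasing order of mutational distance; a join of
j steps inserts j-1 abstract intermediate nodes; pairs whose distance
exceeds the parsimony connection limit stay unconnected, which can leave
the network in several components.

The connection limit is the largest number of steps j for which the
probability of parsimony (no superimposed mutation among the changes
separating two haplotypes) is at least ``alpha`` (conventionally 95%).
The probability is computed from a finite-sites occupancy model: the true
number of mutations K between two sequences is thrown uniformly over the L
sites; a site hit an odd number of times shows a difference, so the number
of observed differences J follows a birth/death walk on 0..L. With a flat
prior over K, P(parsimony | J=j) = P(K=j | J=j).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from haplopop.io_core import HaplotypePartition, PairwiseDifferenceMatrix


def _observed_given_true(L: int, j: int, k_max: int) -> np.ndarray:
    """P(J = j | K = k) for k = 0..k_max under the occupancy walk.

    One mutation moves the count of odd-hit sites from o to o+1 with
    probability (L-o)/L, and back to o-1 with probability o/L.
    """
    probs = np.zeros(k_max + 1)
    state = np.zeros(min(L, k_max) + 2)
    state[0] = 1.0
    if j == 0:
        probs[0] = 1.0
    for k in range(1, k_max + 1):
        new = np.zeros_like(state)
        o = np.arange(state.size)
        up = (L - o).clip(min=0) / L
        down = o / L
        new[1:] += state[:-1] * up[:-1]
        new[:-1] += state[1:] * down[1:]
        state = new
        if j < state.size:
            probs[k] = state[j]
    return probs


def parsimony_probability(
    L: int, j: int, prior: str = "coalescent", tail_tol: float = 1e-12
) -> float:
    """Probability that a j-step difference reflects exactly j mutations.

    ``prior='coalescent'`` weights the true mutation count K by the
    geometric distribution a coalescent implies for a sequence pair, with
    its scale estimated from the pair itself (theta-hat = j); ``'flat'``
    uses an uninformative prior over K. The coalescent prior is the default
    as it follows the pair-coalescent framework the method was built on.
    """
    if j == 0:
        return 1.0
    # only k = j, j+2, j+4, ... can yield J = j
    k_max = j + 400
    probs = _observed_given_true(L, j, k_max)
    terms = probs[j::2]
    if prior == "coalescent":
        t = np.arange(terms.size)
        terms = terms * (j / (j + 1.0)) ** (2 * t)
    elif prior != "flat":
        raise ValueError(f"unknown prior {prior!r}")
    partial = np.cumsum(terms)
    total = partial[-1]
    for t in range(1, terms.size):
        if terms[t] < tail_tol * partial[t]:
            total = partial[t]
            break
    return float(terms[0] / total)


def parsimony_limit(L: int, alpha: float = 0.95, prior: str = "coalescent") -> int:
    """Largest number of steps j with parsimony probability >= alpha.

    Monotone non-increasing in alpha (scanned upward; stops at the first
    step whose parsimony probability drops below alpha).
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    j = 0
    while j < L:
        if parsimony_probability(L, j + 1, prior=prior) < alpha:
            break
        j += 1
    return max(j, 1)  # a single step is always accepted


@dataclass
class ParsimonyNetwork:
    """Haplotype network with observed nodes, intermediates, unit-step edges."""

    graph: nx.Graph
    connection_limit: int
    haplotype_labels: list[str]
    loops_flagged: list[tuple[str, str]] = field(default_factory=list)

    @property
    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    @property
    def observed_nodes(self) -> list[str]:
        return [
            n for n, a in self.graph.nodes(data=True) if not a.get("intermediate")
        ]

    def edge_table(self) -> pd.DataFrame:
        rows = [
            dict(node1=u, node2=v, step=1, loop_member=d.get("loop", False))
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["node1", "node2", "step", "loop_member"])

    def pie_table(self) -> pd.DataFrame:
        """Per-population composition of each observed haplotype node."""
        rows = []
        for n, a in self.graph.nodes(data=True):
            if a.get("intermediate"):
                continue
            for pop, cnt in a.get("pop_counts", {}).items():
                if cnt > 0:
                    rows.append(dict(haplotype=n, population=pop, count=cnt))
        return pd.DataFrame(rows, columns=["haplotype", "population", "count"])

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, a in g.nodes(data=True):
            if "pop_counts" in a:
                a["pop_counts"] = ";".join(
                    f"{p}:{c}" for p, c in a["pop_counts"].items() if c > 0
                )
        nx.write_graphml(g, str(path))


def build_network(
    hp: HaplotypePartition,
    d: PairwiseDifferenceMatrix,
    limit: int | None = None,
    alpha: float = 0.95,
) -> ParsimonyNetwork:
    """Agglomerative statistical-parsimony network.

    Pairs of haplotypes are processed in increasing order of distance;
    within a distance level, pairs involving higher-frequency haplotypes
    connect first (the coalescent expectation that common haplotypes are
    interior). A pair already connected at a shorter distance is skipped;
    a pair connected only at the same distance level adds an alternative
    path, which is retained and flagged as a loop.
    """
    if hp.k < 1:
        raise ValueError("need at least one haplotype")
    if limit is None:
        limit = parsimony_limit(d.L_effective, alpha)
    freq = hp.haplotype_counts
    labels = hp.labels
    g = nx.Graph()
    for i, lab in enumerate(labels):
        pop_counts = {
            pop: int(hp.counts.loc[pop].iloc[i]) for pop in hp.counts.index
        }
        g.add_node(
            lab,
            frequency=int(freq[i]),
            sequence=hp.haplotypes[i],
            intermediate=False,
            pop_counts=pop_counts,
        )
    pairs = sorted(
        itertools.combinations(range(hp.k), 2),
        key=lambda ij: (
            d.d[ij],
            -max(freq[ij[0]], freq[ij[1]]),
            -min(freq[ij[0]], freq[ij[1]]),
            ij,
        ),
    )
    loops: list[tuple[str, str]] = []
    mid_counter = 0
    current_level = None
    components_at_level_start: dict[str, int] = {}

    def comp_ids() -> dict[str, int]:
        return {
            n: ci
            for ci, comp in enumerate(nx.connected_components(g))
            for n in comp
        }

    for i, j in pairs:
        dij = int(d.d[i, j])
        if dij == 0 or dij > limit:
            continue
        if dij != current_level:
            current_level = dij
            components_at_level_start = comp_ids()
        a, b = labels[i], labels[j]
        if components_at_level_start[a] == components_at_level_start[b]:
            continue  # already linked at a shorter distance
        if nx.has_path(g, a, b):
            loops.append((a, b))  # equal-length alternative: keep, flag
        prev = a
        for step in range(1, dij):
            mid_counter += 1
            mid = f"m{mid_counter}"
            g.add_node(mid, frequency=0, intermediate=True)
            g.add_edge(prev, mid, loop=False)
            prev = mid
        g.add_edge(prev, b, loop=False)
        if loops and loops[-1] == (a, b):
            # mark the whole alternative path
            node = prev
            g.edges[node, b]["loop"] = True
    return ParsimonyNetwork(
        graph=g,
        connection_limit=limit,
        haplotype_labels=labels,
        loops_flagged=loops,
    )
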