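"""Distance-based population structure: AMOVA, pairwise Phi_ST, Mantel test.

AMOVA partitions squared molecular distances between individuals across a
group / population / individual hierarchy and converts the mean squares to
variance components with the standard unequal-sample-size coefficients.
Phi-statistics are ratios of those components; their significance comes
from label permutations at the level each statistic describes:

* Phi_ST — individuals permuted among populations (ignoring groups),
* Phi_SC — individuals permuted among populations within their group,
* Phi_CT — whole populations permuted among groups.

All permutation p-values use the (hits + 1) / (B + 1) convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from haplopop.io_core import HaplotypePartition, PairwiseDifferenceMatrix


class HierarchyError(ValueError):
    """Raised for group structures that do not partition the populations."""


@dataclass
class Hierarchy:
    """Grouping of populations for hierarchical AMOVA.

    ``groups`` maps a group label to the list of population labels it
    contains. A single group means a one-level (populations-only) analysis.
    """

    groups: dict[str, list[str]]
    name: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g, pops in self.groups.items():
            if len(pops) < 1:
                raise HierarchyError(f"group {g!r} contains no population")
            dup = seen.intersection(pops)
            if dup:
                raise HierarchyError(f"populations in several groups: {sorted(dup)}")
            seen.update(pops)

    @property
    def populations(self) -> list[str]:
        return [p for pops in self.groups.values() for p in pops]

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class AmovaResult:
    """AMOVA table, Phi-statistics and permutation p-values."""

    df: dict[str, int]
    ss: dict[str, float]
    sigma2: dict[str, float]
    percent: dict[str, float]
    phi_ST: float
    phi_CT: float | None
    phi_SC: float | None
    p_ST: float
    p_CT: float | None
    p_SC: float | None
    n_perms: int
    seed: int
    hierarchy_name: str = ""

    def to_table(self) -> pd.DataFrame:
        rows = []
        for level in self.df:
            rows.append(
                dict(
                    source=level,
                    df=self.df[level],
                    sum_of_squares=self.ss[level],
                    variance_component=self.sigma2[level],
                    percent_variation=self.percent[level],
                )
            )
        return pd.DataFrame(rows)


def _individual_arrays(
    hp: HaplotypePartition, populations: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Expand haplotype counts to per-individual (hap_index, pop_index)."""
    missing = [p for p in populations if p not in hp.counts.index]
    if missing:
        raise HierarchyError(f"populations absent from data: {missing}")
    hap_idx = []
    pop_idx = []
    for pi, pop in enumerate(populations):
        row = hp.counts.loc[pop].to_numpy()
        for h, c in enumerate(row):
            hap_idx.extend([h] * int(c))
            pop_idx.extend([pi] * int(c))
    return np.asarray(hap_idx, dtype=np.int64), np.asarray(pop_idx, dtype=np.int64)


def _pair_sum(counts: np.ndarray, D2: np.ndarray) -> float:
    """Sum of delta^2 over unordered pairs of individuals given hap counts."""
    return 0.5 * float(counts @ D2 @ counts)  # diagonal of D2 is zero


def _amova_components(
    hap: np.ndarray,
    pop_of_ind: np.ndarray,
    group_of_pop: np.ndarray,
    D2: np.ndarray,
    pop_sizes: np.ndarray,
) -> dict:
    """Sums of squares and variance components for one labelling."""
    K = D2.shape[0]
    N = hap.size
    P = pop_sizes.size
    G = int(group_of_pop.max()) + 1

    c_tot = np.bincount(hap, minlength=K).astype(float)
    ss_total = _pair_sum(c_tot, D2) / N

    # per-population and per-group haplotype counts
    C_pop = np.zeros((P, K))
    np.add.at(C_pop, (pop_of_ind, hap), 1.0)
    n_p = pop_sizes.astype(float)
    ss_wp = sum(_pair_sum(C_pop[p], D2) / n_p[p] for p in range(P))

    n_g = np.bincount(group_of_pop, weights=n_p, minlength=G)
    C_grp = np.zeros((G, K))
    np.add.at(C_grp, group_of_pop, C_pop)
    ss_wg = sum(_pair_sum(C_grp[g], D2) / n_g[g] for g in range(G))

    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg

    df_wp = N - P
    sigma_c = (ss_wp / df_wp) if df_wp > 0 else 0.0

    A_g = np.bincount(group_of_pop, weights=n_p**2, minlength=G)
    if G == 1:
        df_ap = P - 1
        ms_ap = ss_ap / df_ap
        n0 = (N - float(np.sum(n_p**2)) / N) / (P - 1)
        sigma_a = (ms_ap - sigma_c) / n0
        total = sigma_a + sigma_c
        return dict(
            levels=("among_populations", "within_populations"),
            df={"among_populations": df_ap, "within_populations": df_wp},
            ss={"among_populations": ss_ap, "within_populations": ss_wp},
            sigma2={"among_populations": sigma_a, "within_populations": sigma_c},
            phi_ST=sigma_a / total if total != 0 else np.nan,
            phi_CT=None,
            phi_SC=None,
            total=total,
        )

    df_ag = G - 1
    df_ap = P - G
    ms_ag = ss_ag / df_ag
    ms_ap = ss_ap / df_ap if df_ap > 0 else 0.0
    # unequal-size coefficients of the expected mean squares
    n_coef = (N - float(np.sum(A_g / n_g))) / (P - G) if P > G else 0.0
    n_coef2 = (float(np.sum(A_g / n_g)) - float(np.sum(n_p**2)) / N) / (G - 1)
    n_coef3 = (N - float(np.sum(n_g**2)) / N) / (G - 1)

    sigma_b = (ms_ap - sigma_c) / n_coef if n_coef > 0 else 0.0
    sigma_a = (ms_ag - sigma_c - n_coef2 * sigma_b) / n_coef3
    total = sigma_a + sigma_b + sigma_c
    return dict(
        levels=(
            "among_groups",
            "among_populations_within_groups",
            "within_populations",
        ),
        df={
            "among_groups": df_ag,
            "among_populations_within_groups": df_ap,
            "within_populations": df_wp,
        },
        ss={
            "among_groups": ss_ag,
            "among_populations_within_groups": ss_ap,
            "within_populations": ss_wp,
        },
        sigma2={
            "among_groups": sigma_a,
            "among_populations_within_groups": sigma_b,
            "within_populations": sigma_c,
        },
        phi_ST=(sigma_a + sigma_b) / total if total != 0 else np.nan,
        phi_CT=sigma_a / total if total != 0 else np.nan,
        phi_SC=sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else np.nan,
        total=total,
    )


def amova(
    hp: HaplotypePartition,
    d: PairwiseDifferenceMatrix,
    hier: Hierarchy,
    n_perms: int = 10000,
    seed: int = 0,
    squared: bool = True,
) -> AmovaResult:
    """Hierarchical AMOVA on a haplotype partition.

    ``squared=True`` uses the squared number of pairwise differences as the
    squared molecular distance; ``squared=False`` uses the raw difference
    count itself (the pairwise-difference convention of some programs).
    Negative variance components are reported as-is.
    """
    populations = hier.populations
    if len(populations) < 2:
        raise HierarchyError("AMOVA needs at least two populations")
    hap, pop_of_ind = _individual_arrays(hp, populations)
    pop_sizes = np.bincount(pop_of_ind, minlength=len(populations))
    if np.any(pop_sizes == 0):
        empty = [populations[i] for i in np.flatnonzero(pop_sizes == 0)]
        raise HierarchyError(f"empty populations: {empty}")
    group_of_pop = np.concatenate(
        [
            np.full(len(pops), gi, dtype=np.int64)
            for gi, pops in enumerate(hier.groups.values())
        ]
    )
    D2 = (d.d.astype(float) ** 2) if squared else d.d.astype(float)

    obs = _amova_components(hap, pop_of_ind, group_of_pop, D2, pop_sizes)
    rng = np.random.default_rng(seed)
    one_level = hier.n_groups == 1
    flat_groups = np.zeros(len(populations), dtype=np.int64)
    # the Phi_ST permutation null ignores groups, so its observed reference
    # must come from the same one-level decomposition
    obs_st_flat = (
        obs["phi_ST"]
        if one_level
        else _amova_components(hap, pop_of_ind, flat_groups, D2, pop_sizes)["phi_ST"]
    )

    hits_st = hits_sc = hits_ct = 0
    for _ in range(n_perms):
        # Phi_ST: individuals among populations, hierarchy ignored
        perm = rng.permutation(hap)
        r = _amova_components(perm, pop_of_ind, flat_groups, D2, pop_sizes)
        if r["phi_ST"] >= obs_st_flat - 1e-12:
            hits_st += 1
        if one_level:
            continue
        # Phi_SC: individuals among populations within their group
        perm_sc = hap.copy()
        for g in range(hier.n_groups):
            sel = np.flatnonzero(group_of_pop[pop_of_ind] == g)
            perm_sc[sel] = perm_sc[rng.permutation(sel)]
        r = _amova_components(perm_sc, pop_of_ind, group_of_pop, D2, pop_sizes)
        if r["phi_SC"] >= obs["phi_SC"] - 1e-12:
            hits_sc += 1
        # Phi_CT: whole populations among groups
        gperm = group_of_pop[rng.permutation(len(populations))]
        r = _amova_components(hap, pop_of_ind, gperm, D2, pop_sizes)
        if r["phi_CT"] >= obs["phi_CT"] - 1e-12:
            hits_ct += 1

    def pval(hits: int) -> float:
        return (hits + 1) / (n_perms + 1)

    total = obs["total"]
    percent = {
        lvl: (100.0 * obs["sigma2"][lvl] / total if total != 0 else np.nan)
        for lvl in obs["levels"]
    }
    return AmovaResult(
        df=obs["df"],
        ss=obs["ss"],
        sigma2=obs["sigma2"],
        percent=percent,
        phi_ST=obs["phi_ST"],
        phi_CT=obs["phi_CT"],
        phi_SC=obs["phi_SC"],
        p_ST=pval(hits_st) if n_perms > 0 else np.nan,
        p_CT=(pval(hits_ct) if (n_perms > 0 and not one_level) else None),
        p_SC=(pval(hits_sc) if (n_perms > 0 and not one_level) else None),
        n_perms=n_perms,
        seed=seed,
        hierarchy_name=hier.name,
    )


def pairwise_phist(
    hp: HaplotypePartition,
    d: PairwiseDifferenceMatrix,
    populations: list[str] | None = None,
    n_perms: int = 10000,
    seed: int = 0,
    squared: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Phi_ST matrix with permutation p-values.

    Each cell is a two-population one-level AMOVA. Populations of size 1
    are still computed but should be treated as unreliable. Returns
    (phi_matrix, p_matrix) as square DataFrames (diagonal NaN).
    """
    if populations is None:
        populations = list(hp.counts.index)
    P = len(populations)
    if P < 2:
        raise HierarchyError("need at least two populations")
    phi = pd.DataFrame(np.nan, index=populations, columns=populations)
    pmat = pd.DataFrame(np.nan, index=populations, columns=populations)
    for i in range(P):
        for j in range(i + 1, P):
            pair = [populations[i], populations[j]]
            hier = Hierarchy(groups={"all": pair})
            res = amova(
                hp, d, hier, n_perms=n_perms,
                seed=seed + 1000003 * i + j, squared=squared,
            )
            phi.iloc[i, j] = phi.iloc[j, i] = res.phi_ST
            pmat.iloc[i, j] = pmat.iloc[j, i] = res.p_ST
    return phi, pmat


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = running
    return adj


def mantel(
    m1: np.ndarray,
    m2: np.ndarray,
    n_perms: int = 10000,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the strictly-lower-triangle entries;
    the null distribution comes from jointly permuting rows and columns of
    the second matrix. One-tailed p for r >= observed, (hits+1)/(B+1).
    Returns (nan, nan) when either triangle has zero variance.
    """
    a = np.asarray(m1, dtype=float)
    b = np.asarray(m2, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if not (np.allclose(a, a.T) and np.allclose(b, b.T)):
        raise ValueError("matrices must be symmetric")
    n = a.shape[0]
    il = np.tril_indices(n, k=-1)
    x = a[il]
    y = b[il]
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")

    def corr(v: np.ndarray, w: np.ndarray) -> float:
        return float(np.corrcoef(v, w)[0, 1])

    r_obs = corr(x, y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perms):
        perm = rng.permutation(n)
        y_perm = b[np.ix_(perm, perm)][il]
        if corr(x, y_perm) >= r_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perms + 1)
    return r_obs, p


def rank_hierarchies(
    hp: HaplotypePartition,
    d: PairwiseDifferenceMatrix,
    hierarchies: list[Hierarchy],
    n_perms: int = 10000,
    seed: int = 0,
    squared: bool = True,
) -> tuple[pd.DataFrame, list[AmovaResult]]:
    """Evaluate candidate groupings and rank them by among-group variance.

    Mirrors the manual practice of re-running AMOVA over alternative
    geographic groupings and keeping the one maximizing the among-group
    percentage of variance.
    """
    results = []
    for i, hier in enumerate(hierarchies):
        res = amova(hp, d, hier, n_perms=n_perms, seed=seed + i, squared=squared)
        results.append(res)
    rows = []
    for res in results:
        among = res.percent.get("among_groups", res.percent.get("among_populations"))
        rows.append(
            dict(
                hierarchy=res.hierarchy_name,
                among_group_percent=among,
                phi_CT=res.phi_CT,
                p_CT=res.p_CT,
                phi_ST=res.phi_ST,
                p_ST=res.p_ST,
            )
        )
    table = pd.DataFrame(rows).sort_values(
        "among_group_percent", ascending=False, ignore_index=True
    )
    return table, results
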