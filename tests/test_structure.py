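import itertools

import numpy as np
import pytest

from haplopop.structure import (
    Hierarchy,
    HierarchyError,
    amova,
    bh_adjust,
    mantel,
    pairwise_phist,
    rank_hierarchies,
)
from conftest import make_partition


def brute_force_amova(individuals, D2):
    """Independent sums-of-squares oracle.

    ``individuals`` is a list of (group, pop, hap_index); distances squared
    are summed by explicit double loops and the variance components solved
    from the unequal-size expected-mean-square equations.
    """
    N = len(individuals)
    pops = sorted({(g, p) for g, p, _ in individuals})
    groups = sorted({g for g, _, _ in individuals})
    P, G = len(pops), len(groups)

    def pairs_ss(members):
        tot = 0.0
        for (i, j) in itertools.combinations(members, 2):
            tot += D2[individuals[i][2], individuals[j][2]]
        return tot / len(members)

    all_idx = list(range(N))
    ss_total = pairs_ss(all_idx)
    ss_wp = sum(
        pairs_ss([i for i in all_idx if individuals[i][:2] == gp])
        for gp in pops
    )
    ss_wg = sum(
        pairs_ss([i for i in all_idx if individuals[i][0] == g])
        for g in groups
    )
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg
    n_p = {gp: sum(1 for i in all_idx if individuals[i][:2] == gp) for gp in pops}
    n_g = {g: sum(1 for i in all_idx if individuals[i][0] == g) for g in groups}
    sigma_c = ss_wp / (N - P)
    if G == 1:
        n0 = (N - sum(v**2 for v in n_p.values()) / N) / (P - 1)
        sigma_a = (ss_ap / (P - 1) - sigma_c) / n0
        return ss_ap, ss_wp, sigma_a, sigma_c
    A = {g: sum(n_p[gp] ** 2 for gp in pops if gp[0] == g) for g in groups}
    nc = (N - sum(A[g] / n_g[g] for g in groups)) / (P - G)
    nc2 = (sum(A[g] / n_g[g] for g in groups) - sum(v**2 for v in n_p.values()) / N) / (G - 1)
    nc3 = (N - sum(v**2 for v in n_g.values()) / N) / (G - 1)
    sigma_b = (ss_ap / (P - G) - sigma_c) / nc
    sigma_a = (ss_ag / (G - 1) - sigma_c - nc2 * sigma_b) / nc3
    return (ss_ag, ss_ap, ss_wp), (sigma_a, sigma_b, sigma_c)


class TestAmova:
    def test_identical_compositions_phi_near_zero(self):
        hp, d = make_partition({"p1": [20, 20], "p2": [20, 20]}, [[0, 1], [1, 0]])
        res = amova(hp, d, Hierarchy(groups={"all": ["p1", "p2"]}), n_perms=0)
        assert abs(res.phi_ST) < 0.05

    def test_fixed_difference_phi_one(self):
        hp, d = make_partition({"p1": [10, 0], "p2": [0, 10]}, [[0, 1], [1, 0]])
        res = amova(hp, d, Hierarchy(groups={"all": ["p1", "p2"]}), n_perms=200, seed=1)
        assert res.phi_ST == pytest.approx(1.0)
        assert res.sigma2["within_populations"] == pytest.approx(0.0)
        assert res.p_ST < 0.05

    def test_three_population_oracle(self):
        # unequal sizes, 3 haplotypes, non-trivial distances
        counts = {"p1": [4, 1, 0], "p2": [1, 3, 1], "p3": [0, 2, 5]}
        dmat = [[0, 2, 3], [2, 0, 1], [3, 1, 0]]
        hp, d = make_partition(counts, dmat)
        res = amova(hp, d, Hierarchy(groups={"all": ["p1", "p2", "p3"]}), n_perms=0)
        individuals = []
        for g, p in [("all", "p1"), ("all", "p2"), ("all", "p3")]:
            for h, c in enumerate(counts[p]):
                individuals.extend([(g, p, h)] * c)
        D2 = np.asarray(dmat, dtype=float) ** 2
        ss_ap, ss_wp, sigma_a, sigma_c = brute_force_amova(individuals, D2)
        assert res.ss["among_populations"] == pytest.approx(ss_ap, abs=1e-10)
        assert res.ss["within_populations"] == pytest.approx(ss_wp, abs=1e-10)
        assert res.sigma2["among_populations"] == pytest.approx(sigma_a, abs=1e-10)
        assert res.sigma2["within_populations"] == pytest.approx(sigma_c, abs=1e-10)

    def test_two_level_oracle_and_structure(self):
        counts = {"p1": [5, 0, 0], "p2": [4, 1, 0], "p3": [0, 0, 6], "p4": [1, 0, 4]}
        dmat = [[0, 1, 4], [1, 0, 3], [4, 3, 0]]
        hp, d = make_partition(counts, dmat)
        hier = Hierarchy(groups={"west": ["p1", "p2"], "east": ["p3", "p4"]})
        res = amova(hp, d, hier, n_perms=0)
        individuals = []
        for g, p in [("west", "p1"), ("west", "p2"), ("east", "p3"), ("east", "p4")]:
            for h, c in enumerate(counts[p]):
                individuals.extend([(g, p, h)] * c)
        D2 = np.asarray(dmat, dtype=float) ** 2
        (ss_ag, ss_ap, ss_wp), (sa, sb, sc) = brute_force_amova(individuals, D2)
        assert res.ss["among_groups"] == pytest.approx(ss_ag, abs=1e-10)
        assert res.sigma2["among_groups"] == pytest.approx(sa, abs=1e-10)
        assert res.sigma2["among_populations_within_groups"] == pytest.approx(sb, abs=1e-10)
        assert res.sigma2["within_populations"] == pytest.approx(sc, abs=1e-10)
        assert sum(res.percent.values()) == pytest.approx(100.0)
        assert sum(res.df.values()) == hp.n_total - 1
        # strong group split dominates
        assert res.percent["among_groups"] > 50

    def test_df_sum_and_percent_sum(self):
        hp, d = make_partition(
            {"p1": [3, 2], "p2": [2, 3], "p3": [4, 1]}, [[0, 2], [2, 0]]
        )
        res = amova(hp, d, Hierarchy(groups={"g1": ["p1", "p2"], "g2": ["p3"]}), n_perms=0)
        assert sum(res.df.values()) == hp.n_total - 1
        assert sum(res.percent.values()) == pytest.approx(100.0)

    def test_permutation_pvalues_reproducible(self):
        hp, d = make_partition({"p1": [6, 2], "p2": [2, 6]}, [[0, 3], [3, 0]])
        hier = Hierarchy(groups={"all": ["p1", "p2"]})
        r1 = amova(hp, d, hier, n_perms=300, seed=5)
        r2 = amova(hp, d, hier, n_perms=300, seed=5)
        assert r1.p_ST == r2.p_ST

    def test_empty_group_rejected(self):
        with pytest.raises(HierarchyError):
            Hierarchy(groups={"g1": []})


class TestPairwisePhist:
    def test_identical_and_fixed_extremes(self):
        hp, d = make_partition(
            {"p1": [6, 2], "p2": [0, 8], "p3": [6, 2]}, [[0, 1], [1, 0]]
        )
        phi, p = pairwise_phist(hp, d, n_perms=50, seed=3)
        assert phi.loc["p1", "p3"] <= 0.0 + 1e-12  # identical compositions
        assert np.isnan(phi.loc["p1", "p1"])
        assert (phi.values == phi.values.T)[~np.isnan(phi.values)].all()

    def test_matches_per_pair_amova(self):
        hp, d = make_partition(
            {"p1": [5, 2, 1], "p2": [1, 5, 2], "p3": [2, 1, 5], "p4": [3, 3, 2]},
            [[0, 1, 2], [1, 0, 1], [2, 1, 0]],
        )
        phi, _ = pairwise_phist(hp, d, n_perms=0)
        for a, b in itertools.combinations(["p1", "p2", "p3", "p4"], 2):
            res = amova(hp, d, Hierarchy(groups={"all": [a, b]}), n_perms=0)
            assert phi.loc[a, b] == pytest.approx(res.phi_ST, abs=1e-12)


class TestMantel:
    def test_perfect_linearity(self, rng):
        m = rng.uniform(1, 5, size=(6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        r, p = mantel(m, 2 * m, n_perms=200, seed=0)
        assert r == pytest.approx(1.0)
        assert p < 0.05

    def test_constant_matrix_undefined(self):
        m1 = np.array([[0, 1.0], [1.0, 0]])
        m2 = np.array([[0, 1.0], [1.0, 0]])
        m2[:] = np.where(np.eye(2, dtype=bool), 0, 3.0)
        r, p = mantel(m1, m2, n_perms=10)
        assert np.isnan(r) and np.isnan(p)

    def test_r_matches_direct_triangle_correlation(self, rng):
        a = rng.uniform(0, 10, size=(8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = rng.uniform(0, 10, size=(8, 8))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        r, _ = mantel(a, b, n_perms=10, seed=0)
        il = np.tril_indices(8, -1)
        assert r == pytest.approx(np.corrcoef(a[il], b[il])[0, 1], abs=1e-12)

    def test_agrees_with_scikit_bio(self, rng):
        from skbio.stats.distance import DistanceMatrix, mantel as skbio_mantel

        a = rng.uniform(0, 10, size=(7, 7))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = a + rng.uniform(0, 3, size=(7, 7))
        b = (b + b.T) / 2
        np.fill_diagonal(b, 0)
        r, _ = mantel(a, b, n_perms=50, seed=0)
        result = skbio_mantel(
            DistanceMatrix(a), DistanceMatrix(b), method="pearson",
            permutations=0, alternative="greater",
        )
        sk_r = result[0] if isinstance(result, tuple) else result.statistic
        assert r == pytest.approx(float(sk_r), abs=1e-10)


class TestRankHierarchies:
    def test_orders_by_among_group_percent(self):
        counts = {"p1": [9, 0], "p2": [8, 1], "p3": [1, 8], "p4": [0, 9]}
        hp, d = make_partition(counts, [[0, 5], [5, 0]])
        good = Hierarchy(groups={"a": ["p1", "p2"], "b": ["p3", "p4"]}, name="good")
        bad = Hierarchy(groups={"a": ["p1", "p3"], "b": ["p2", "p4"]}, name="bad")
        table, _ = rank_hierarchies(hp, d, [bad, good], n_perms=0)
        assert table.iloc[0]["hierarchy"] == "good"


def test_bh_adjust_monotone_and_bounded(rng):
    p = rng.uniform(0, 1, size=20)
    adj = bh_adjust(p)
    assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
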