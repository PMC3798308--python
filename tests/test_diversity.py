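import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haplopop.diversity import (
    diversity_table,
    fus_Fs,
    haplotype_diversity,
    mean_pairwise_differences,
    neutrality_pvalues,
    nucleotide_diversity,
    tajimas_D,
)
from haplopop.io_core import collapse_haplotypes, pairwise_differences, segregating_sites
from conftest import make_alignment


class TestHaplotypeDiversity:
    def test_monomorphic_zero(self):
        h, sd = haplotype_diversity([5])
        assert h == 0.0 and sd == 0.0

    def test_two_distinct_n2_is_one(self):
        h, _ = haplotype_diversity([1, 1])
        assert h == pytest.approx(1.0)

    def test_hand_value(self):
        # (5/4)(1 - 11/25) = 0.7
        h, sd = haplotype_diversity([3, 1, 1])
        assert h == pytest.approx(0.7)
        assert sd > 0

    def test_insufficient_sample_undefined(self):
        h, sd = haplotype_diversity([1])
        assert math.isnan(h) and math.isnan(sd)

    def test_invariant_under_relabeling(self, rng):
        counts = rng.integers(1, 10, size=6)
        h1, s1 = haplotype_diversity(counts)
        h2, s2 = haplotype_diversity(counts[::-1])
        assert h1 == pytest.approx(h2) and s1 == pytest.approx(s2)


class TestNucleotideDiversity:
    def test_monomorphic_zero(self):
        aln = make_alignment(["ACGT"] * 5)
        hp = collapse_haplotypes(aln)
        pi, _ = nucleotide_diversity(hp, pairwise_differences(hp))
        assert pi == 0.0

    def test_two_sequences_one_difference(self):
        aln = make_alignment(["AAAAAAAAAA", "AAAAAAAAAT"])
        hp = collapse_haplotypes(aln)
        pi, _ = nucleotide_diversity(hp, pairwise_differences(hp))
        assert pi == pytest.approx(0.1)

    def test_matches_all_pairs_brute_force(self, rng):
        base = rng.choice(list("ACGT"), size=30)
        seqs = []
        for _ in range(10):
            row = base.copy()
            for site in rng.choice(30, size=rng.integers(0, 4), replace=False):
                row[site] = rng.choice(list("ACGT"))
            seqs.append("".join(row))
        aln = make_alignment(seqs)
        hp = collapse_haplotypes(aln)
        d = pairwise_differences(hp)
        pi, _ = nucleotide_diversity(hp, d)
        brute = np.mean(
            [
                sum(a != b for a, b in zip(s1, s2)) / 30
                for s1, s2 in itertools.combinations(seqs, 2)
            ]
        )
        assert pi == pytest.approx(brute, abs=1e-12)
        assert mean_pairwise_differences(hp, d) == pytest.approx(pi * 30)


def independent_tajima_D(n, S, pi_hat):
    """Second implementation straight from the published constants, in
    exact rational arithmetic until the final square root."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_hat - S / float(a1)) / math.sqrt(float(var))


class TestTajimasD:
    def test_no_segregating_sites_undefined(self):
        assert math.isnan(tajimas_D(10, 0, 0.0))

    def test_small_n_undefined(self):
        assert math.isnan(tajimas_D(3, 5, 2.0))

    def test_zero_numerator(self):
        a1 = sum(1.0 / i for i in range(1, 10))
        assert tajimas_D(10, 5, 5 / a1) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n,S,pi_hat", [(6, 3, 1.4), (10, 7, 2.1), (12, 13, 6.5)])
    def test_matches_independent_formula(self, n, S, pi_hat):
        assert tajimas_D(n, S, pi_hat) == pytest.approx(
            independent_tajima_D(n, S, pi_hat), abs=1e-10
        )

    def test_alignment_summaries_roundtrip(self, random_alignment):
        hp = collapse_haplotypes(random_alignment)
        d = pairwise_differences(hp)
        S = segregating_sites(random_alignment)
        mpd = mean_pairwise_differences(hp, d)
        if S > 0:
            assert tajimas_D(random_alignment.n, S, mpd) == pytest.approx(
                independent_tajima_D(random_alignment.n, S, mpd), abs=1e-10
            )


def exact_stirling_unsigned(n):
    """Integer unsigned Stirling numbers of the first kind, row n."""
    row = [1]  # |s(0,0)|
    for m in range(1, n + 1):
        new = [0] * (m + 1)
        for k in range(1, m + 1):
            new[k] = (row[k - 1] if k - 1 < len(row) else 0) + (
                (m - 1) * row[k] if k < len(row) else 0
            )
        row = new
    return row


def exact_fs(n, k_obs, theta: Fraction) -> float:
    """Fu's Fs via exact rational arithmetic (oracle for small n)."""
    s = exact_stirling_unsigned(n)
    rising = Fraction(1)
    for i in range(n):
        rising *= theta + i
    probs = [Fraction(s[k]) * theta**k / rising for k in range(1, n + 1)]
    s_prime = sum(probs[k_obs - 1 :])
    return math.log(float(s_prime) / float(1 - s_prime))


class TestFusFs:
    def test_exhaustive_n4(self):
        # |s(4,.)| = 6, 11, 6, 1; theta = 1 -> S' = 18/24, Fs = ln 3
        assert fus_Fs(4, 2, 1.0) == pytest.approx(math.log(3.0), abs=1e-10)

    def test_k1_undefined(self):
        assert math.isnan(fus_Fs(10, 1, 2.0))

    def test_zero_theta_undefined(self):
        assert math.isnan(fus_Fs(10, 3, 0.0))

    @pytest.mark.parametrize(
        "n,k,theta",
        [(6, 3, Fraction(1, 2)), (8, 5, Fraction(2)), (12, 4, Fraction(7, 3)),
         (12, 12, Fraction(5)), (10, 2, Fraction(1, 10))],
    )
    def test_matches_exact_rational_oracle(self, n, k, theta):
        # log-space recursion against exact arithmetic, 10 significant digits
        got = fus_Fs(n, k, float(theta))
        want = exact_fs(n, k, theta)
        assert got == pytest.approx(want, rel=1e-10, abs=1e-10)

    def test_large_n_finite(self):
        val = fus_Fs(200, 40, 3.5)
        assert math.isfinite(val)


class TestNeutralityPvalues:
    def test_reproducible_under_seed(self):
        r1 = neutrality_pvalues(15, -1.0, -2.0, 2.0, n_sims=200, seed=42)
        r2 = neutrality_pvalues(15, -1.0, -2.0, 2.0, n_sims=200, seed=42)
        assert r1.p_D == r2.p_D and r1.p_Fs == r2.p_Fs

    def test_median_observation_near_half(self, rng):
        # observed statistic at the simulation median -> p ~ 0.5
        from haplopop.synthetic_data import coalescent_summaries

        sims = []
        for _ in range(400):
            S, pi, k = coalescent_summaries(15, 3.0, rng)
            D = tajimas_D(15, S, pi)
            sims.append(0.0 if not math.isfinite(D) else D)
        med = float(np.median(sims))
        res = neutrality_pvalues(15, med, float("nan"), 3.0, n_sims=400, seed=9)
        assert 0.35 < res.p_D < 0.65

    def test_star_expansion_fs_significant(self):
        from haplopop.synthetic_data import simulate_star_expansion

        sig = total = 0
        for seed in range(15):
            sam = simulate_star_expansion(60, 1.5, L=300, seed=seed)
            hp = collapse_haplotypes(sam.to_alignment())
            d = pairwise_differences(hp)
            mpd = mean_pairwise_differences(hp, d)
            Fs = fus_Fs(60, hp.k, mpd)
            if not math.isfinite(Fs):
                continue
            total += 1
            res = neutrality_pvalues(
                60, float("nan"), Fs, mpd, n_sims=200, seed=seed
            )
            sig += res.p_Fs < 0.05
        assert total >= 10 and sig > total / 2


class TestDiversityTable:
    def test_pooled_matches_single_population(self):
        aln = make_alignment(
            ["AAAA", "AAAT", "AATT", "AAAA"], ["p1"] * 4
        )
        tab = diversity_table(aln, n_sims=0)
        pooled = tab[tab.site == "pooled"].iloc[0]
        per = tab[tab.site == "p1"].iloc[0]
        for col in ("n", "k", "h", "pi", "S"):
            assert pooled[col] == per[col]
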