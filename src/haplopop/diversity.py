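"""Diversity indices and neutrality tests for haplotype samples.

Haplotype diversity h and nucleotide diversity pi follow Nei's unbiased
estimators with their standard sampling variances. Tajima's D is the
normalized gap between the pairwise-difference and segregating-site
estimators of theta. Fu's Fs is the log-odds of drawing at least the
observed number of distinct haplotypes under the Ewens sampling formula
with theta set to the mean number of pairwise differences.

Significance of D and Fs is assessed by neutral-coalescent simulation
conditioned on the sample size and the observed theta_pi, mirroring the
approach of the standard population-genetics packages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable

import numpy as np
import pandas as pd

from haplopop.io_core import (
    HaplotypePartition,
    LocusAlignment,
    PairwiseDifferenceMatrix,
    collapse_haplotypes,
    pairwise_differences,
    segregating_sites,
)

UNDEFINED = float("nan")


@dataclass
class DiversityResult:
    """Per-sample diversity summary for one locus."""

    n: int
    k: int
    h: float
    sd_h: float
    pi: float
    sd_pi: float
    S: int
    mean_pairwise_diff: float
    L_effective: int


@dataclass
class NeutralityResult:
    tajima_D: float
    fu_Fs: float
    p_D: float
    p_Fs: float
    n_sims: int
    seed: int
    reason_D: str | None = None
    reason_Fs: str | None = None


def haplotype_diversity(counts) -> tuple[float, float]:
    """Nei's unbiased haplotype (gene) diversity and its standard deviation.

    h = n/(n-1) (1 - sum p_i^2); the variance is Nei (1987) eq. 8.12.
    Returns (nan, nan) for n < 2.
    """
    c = np.asarray(counts, dtype=float)
    c = c[c > 0]
    n = c.sum()
    if n < 2:
        return UNDEFINED, UNDEFINED
    p = c / n
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    h = n / (n - 1.0) * (1.0 - sum2)
    var = (
        2.0
        / (n * (n - 1.0))
        * (2.0 * (n - 2.0) * (sum3 - sum2**2) + sum2 - sum2**2)
    )
    return h, math.sqrt(max(var, 0.0))


def mean_pairwise_differences(
    hp: HaplotypePartition, d: PairwiseDifferenceMatrix
) -> float:
    """Mean number of differing sites over all sequence pairs (theta_pi)."""
    c = hp.haplotype_counts.astype(float)
    n = c.sum()
    if n < 2:
        return UNDEFINED
    total = 0.5 * float(c @ d.d @ c)  # diagonal is zero
    return total / (n * (n - 1.0) / 2.0)


def nucleotide_diversity(
    hp: HaplotypePartition, d: PairwiseDifferenceMatrix
) -> tuple[float, float]:
    """Nucleotide diversity per site with its total standard deviation.

    pi equals the mean pairwise difference divided by the number of compared
    sites; the variance includes both sampling and stochastic (coalescent)
    components, following the standard total-variance formula.
    """
    n = hp.n_total
    if n < 2:
        return UNDEFINED, UNDEFINED
    L = d.L_effective
    if L < 1:
        raise ValueError("L_effective must be >= 1")
    pi = mean_pairwise_differences(hp, d) / L
    var = (n + 1.0) / (3.0 * (n - 1.0)) * pi / L + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return pi, math.sqrt(max(var, 0.0))


def _tajima_constants(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajimas_D(n: int, S: int, mean_pairwise_diff: float) -> float:
    """Tajima's D from sample size, segregating sites and mean differences.

    Undefined (nan) when S = 0 or n < 4.
    """
    if n < 4 or S <= 0:
        return UNDEFINED
    a1 = sum(1.0 / i for i in range(1, n))
    e1, e2 = _tajima_constants(n)
    var = e1 * S + e2 * S * (S - 1.0)
    if var <= 0:
        return UNDEFINED
    return (mean_pairwise_diff - S / a1) / math.sqrt(var)


@lru_cache(maxsize=64)
def _log_stirling_row(n: int) -> tuple[float, ...]:
    """log |s(n,k)| for k=0..n (unsigned Stirling numbers, first kind).

    Row-by-row recursion |s(n,k)| = |s(n-1,k-1)| + (n-1)|s(n-1,k)| carried
    in log space so that n in the hundreds stays finite.
    """
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        shifted = row[0:m]  # |s(m-1, k-1)| for k = 1..m
        if m == 1:
            new[1] = shifted[0]
        else:
            new[1 : m + 1] = np.logaddexp(
                shifted, math.log(m - 1) + row[1 : m + 1]
            )
        row = new
    return tuple(row)


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """P(K = k) for k=1..n under the Ewens sampling formula.

    P(K=k) = |s(n,k)| theta^k / theta^(n rising).
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    log_s = np.array(_log_stirling_row(n)[1:])  # k = 1..n
    k = np.arange(1, n + 1)
    log_rising = sum(math.log(theta + i) for i in range(n))
    return _normalized(log_s + k * math.log(theta) - log_rising)


def _normalized(logp: np.ndarray) -> np.ndarray:
    m = logp.max()
    p = np.exp(logp - m)
    return p / p.sum()


def fus_Fs(n: int, k_obs: int, theta_pi: float) -> float:
    """Fu's Fs statistic.

    S' = P(K >= k_obs) under the Ewens distribution with theta = theta_pi;
    Fs = ln(S' / (1 - S')). Undefined (nan) when k_obs = 1 (S' = 1) or
    theta_pi <= 0.
    """
    if n < 2 or not (1 <= k_obs <= n):
        return UNDEFINED
    if k_obs == 1 or theta_pi <= 0 or not math.isfinite(theta_pi):
        return UNDEFINED
    p = _normalized(
        np.array(_log_stirling_row(n)[1:])
        + np.arange(1, n + 1) * math.log(theta_pi)
        - sum(math.log(theta_pi + i) for i in range(n))
    )
    s_prime = float(p[k_obs - 1 :].sum())
    if s_prime <= 0.0 or s_prime >= 1.0:
        return UNDEFINED
    return math.log(s_prime / (1.0 - s_prime))


def neutrality_pvalues(
    n: int,
    obs_D: float,
    obs_Fs: float,
    theta_pi: float,
    n_sims: int = 1000,
    seed: int = 0,
    simulator: Callable[..., tuple[int, float, int]] | None = None,
    tail: str = "lower",
) -> NeutralityResult:
    """Simulation p-values for Tajima's D and Fu's Fs.

    Neutral coalescent samples are drawn conditional on n with
    theta = observed theta_pi; p is the fraction of simulated statistics at
    or below the observed value (lower tail, the population-expansion
    alternative) or twice the smaller tail when ``tail='two'``.

    Simulated samples without polymorphism contribute D = 0; monomorphic
    simulated samples (k = 1) have S' = 1 and sit at the upper extreme of
    Fs, counting against a low observed Fs.
    """
    if simulator is None:
        from haplopop.synthetic_data import coalescent_summaries

        simulator = coalescent_summaries
    rng = np.random.default_rng(seed)
    sim_D = np.empty(n_sims)
    sim_Fs = np.empty(n_sims)
    for b in range(n_sims):
        S, pi_hat, k = simulator(n, theta_pi, rng)
        Dval = tajimas_D(n, S, pi_hat)
        sim_D[b] = 0.0 if not math.isfinite(Dval) else Dval
        Fsval = fus_Fs(n, k, pi_hat)
        sim_Fs[b] = np.inf if not math.isfinite(Fsval) else Fsval

    def tail_p(sims: np.ndarray, obs: float) -> float:
        if not math.isfinite(obs):
            return UNDEFINED
        lower = float(np.mean(sims <= obs))
        if tail == "lower":
            return lower
        upper = float(np.mean(sims >= obs))
        return min(1.0, 2.0 * min(lower, upper))

    return NeutralityResult(
        tajima_D=obs_D,
        fu_Fs=obs_Fs,
        p_D=tail_p(sim_D, obs_D),
        p_Fs=tail_p(sim_Fs, obs_Fs),
        n_sims=n_sims,
        seed=seed,
        reason_D=None if math.isfinite(obs_D) else "undefined statistic",
        reason_Fs=None if math.isfinite(obs_Fs) else "undefined statistic",
    )


def diversity_result(
    hp: HaplotypePartition, d: PairwiseDifferenceMatrix, S: int
) -> DiversityResult:
    h, sd_h = haplotype_diversity(hp.haplotype_counts)
    pi, sd_pi = nucleotide_diversity(hp, d)
    return DiversityResult(
        n=hp.n_total,
        k=hp.k,
        h=h,
        sd_h=sd_h,
        pi=pi,
        sd_pi=sd_pi,
        S=S,
        mean_pairwise_diff=mean_pairwise_differences(hp, d),
        L_effective=d.L_effective,
    )


def _subset_alignment(aln: LocusAlignment, sample_ids: list[str]) -> LocusAlignment:
    idx = [aln.sample_ids.index(s) for s in sample_ids]
    return LocusAlignment(
        locus_name=aln.locus_name,
        sample_ids=list(sample_ids),
        matrix=aln.matrix[idx, :],
        population_of={s: aln.population_of[s] for s in sample_ids},
    )


def diversity_table(
    aln: LocusAlignment,
    site_policy: str = "complete_deletion",
    n_sims: int = 1000,
    seed: int = 0,
    per_population: bool = True,
) -> pd.DataFrame:
    """Per-population and pooled diversity / neutrality report.

    One row per population plus a 'pooled' row: n, k, h +- SD, pi +- SD, S,
    Tajima's D (p), Fu's Fs (p). The site set (and hence L_effective) is the
    pooled complete-deletion set, so per-population and pooled statistics
    are computed over a common window.
    """
    rows = []
    units: list[tuple[str, list[str]]] = []
    if per_population:
        by_pop: dict[str, list[str]] = {}
        for s in aln.sample_ids:
            by_pop.setdefault(aln.population_of[s], []).append(s)
        units.extend(by_pop.items())
    units.append(("pooled", list(aln.sample_ids)))
    for i, (name, samples) in enumerate(units):
        sub = _subset_alignment(aln, samples)
        hp = collapse_haplotypes(sub, site_policy)
        d = pairwise_differences(hp)
        S = segregating_sites(sub, site_policy)
        res = diversity_result(hp, d, S)
        D = tajimas_D(res.n, res.S, res.mean_pairwise_diff)
        Fs = fus_Fs(res.n, res.k, res.mean_pairwise_diff)
        if (
            n_sims > 0
            and res.mean_pairwise_diff > 0
            and (math.isfinite(D) or math.isfinite(Fs))
        ):
            nt = neutrality_pvalues(
                res.n, D, Fs, res.mean_pairwise_diff,
                n_sims=n_sims, seed=seed + i,
            )
            p_D, p_Fs = nt.p_D, nt.p_Fs
        else:
            p_D = p_Fs = UNDEFINED
        rows.append(
            dict(
                site=name, n=res.n, k=res.k,
                h=res.h, sd_h=res.sd_h, pi=res.pi, sd_pi=res.sd_pi,
                S=res.S, mean_pairwise_diff=res.mean_pairwise_diff,
                tajima_D=D, p_D=p_D, fu_Fs=Fs, p_Fs=p_Fs,
            )
        )
    return pd.DataFrame(rows)
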