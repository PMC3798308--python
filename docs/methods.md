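# Methods

This note documents the models, estimators and numerical choices behind
`haplopop`, and what the synthetic-data generators do and do not emulate.

## Data model and site handling

A locus is an equal-length nucleotide alignment with one row per sample
and a sample → population map. IUPAC ambiguity codes other than N are
collapsed to N on input (the intended regime is Sanger-quality organellar
or ribosomal markers where ambiguity is rare). Two site policies exist:

* `complete_deletion` (default): every column containing `-` or `N` in
  *any* sequence is removed before haplotypes are compared. All statistics
  then share one common site set, which is what the diversity indices and
  the neutrality tests assume.
* `pairwise`: all columns retained. Offered for completeness; mixing it
  with Tajima's *D* or Fu's *Fs* is inconsistent (the site set differs
  between pairs) and the default never does so.

Sites are 0-based internally and 1-based in reports. No realignment is
performed; inputs are assumed pre-trimmed to a common window per locus.
Haplotypes are stored in order of first appearance; display labels
H1..Hk rank by total frequency (ties by first appearance) so outputs are
stable across runs.

## Diversity and neutrality

Haplotype diversity uses the unbiased estimator h = n/(n−1)(1 − Σp_i²)
with Nei's sampling variance. Nucleotide diversity π is the mean number
of pairwise differences divided by the number of retained sites; its
standard deviation includes the stochastic (coalescent) component, i.e.
the "total variance" commonly reported alongside π.

Tajima's *D* is computed from (n, S, mean pairwise differences) with the
published normalizing constants; it is undefined for S = 0 or n < 4.
Fu's *Fs* is ln(S′/(1−S′)) with S′ = P(K ≥ k_obs) under the Ewens sampling
formula at θ = θ_π (the mean pairwise differences — the conventional
plug-in). Unsigned Stirling numbers of the first kind are carried in log
space via |s(n,k)| = |s(n−1,k−1)| + (n−1)|s(n−1,k)|, which stays finite
for n well beyond 200; the test suite pins the recursion against exact
rational arithmetic for n ≤ 12.

Significance of both statistics comes from neutral-coalescent simulation
conditioned on n with θ set to the observed θ_π (the standard, simpler
alternative to conditioning on S; *D* is nearly pivotal in θ so the
approximation is mild). p-values are lower-tailed by default (the
expansion alternative); a two-tailed variant is available. Simulated
replicates without polymorphism contribute D = 0; monomorphic replicates
sit at the upper extreme of Fs (S′ = 1). The conventional stricter
significance threshold for Fs (0.02 rather than 0.05) applies to the
reported p-values; both cutoffs are a reader's choice, not baked in.
Default 1000 simulations, explicit seed everywhere.

## AMOVA, Φ-statistics, Mantel

AMOVA partitions squared molecular distances between individuals.
Following the classical squared-distance decomposition, the default
squared distance is the *square* of the number of differing sites
(`squared=True`); the raw-count convention used by some programs is one
flag away. Sums of squares are computed from haplotype count vectors
(½·cᵀD²c per stratum), variance components from the expected mean squares
with the standard unequal-size coefficients, and

Φ_CT = σ²_a/σ²_T, Φ_SC = σ²_b/(σ²_b+σ²_c), Φ_ST = (σ²_a+σ²_b)/σ²_T.

Negative components are reported as-is (not truncated); percentages are
taken on the summed components. Permutation schemes: individuals among
populations (Φ_ST, hierarchy ignored — the observed reference for this
test is likewise the one-level decomposition), individuals among
populations within groups (Φ_SC), whole populations among groups (Φ_CT);
p = (hits+1)/(B+1). A single supplied group collapses to the one-level
analysis, and a two-population one-level AMOVA is exactly the pairwise
Φ_ST cell. Populations of size 1 are computed but should be read as
unreliable. Pairwise p-value matrices come with Benjamini–Hochberg
adjusted companions, both labeled.

The "tested iteratively" practice of re-grouping populations until the
among-group variance peaks is implemented as explicit enumeration of
user-supplied candidate hierarchies ranked by among-group percent; no
automatic combinatorial search is attempted.

The Mantel statistic is the Pearson correlation of strictly-lower-triangle
entries; the null permutes rows and columns of the second matrix jointly;
p is one-tailed for r ≥ observed with the same +1 convention.

## Statistical-parsimony networks

The connection limit is the largest step count j whose probability of
parsimony is ≥ α (default 0.95). The probability model: the true number
of mutations K separating two sequences lands uniformly on the L retained
sites; a site hit an odd number of times shows a difference, so the
observed difference count performs a walk on 0..L with up-probability
(L−o)/L. P(J=j | K=k) is computed exactly by dynamic programming, and the
posterior P(K=j | J=j) uses a geometric prior over K — the distribution a
pair coalescent implies — with its scale estimated from the pair itself
(θ̂ = j). A flat prior is available (`prior="flat"`); it is more
conservative by one to two steps at typical lengths. For reference, the
default gives limits of 3/5/5 steps for 163/294/379-bp loci and 7 steps
at 654 bp. This is our own derivation in the spirit of the published
parsimony-probability equations; it is not guaranteed to equal the
original TCS program step-for-step.

Construction is agglomerative: haplotype pairs in increasing distance
order, ties broken toward the higher-frequency haplotype (the coalescent
expectation that common haplotypes are interior); a j-step join inserts
j−1 abstract intermediate nodes (no concrete sequences — several
mutational orderings are equally consistent); pairs already connected at
a shorter distance are skipped; equal-length alternative connections are
retained and flagged as loops rather than silently resolved; pairs beyond
the limit stay unconnected, possibly splitting the network.

## Mismatch distributions and expansion dating

The sudden-expansion expectation follows from the pair coalescent with an
instantaneous size change θ₀ → θ₁ at mutational time τ before present:

F_j(τ,θ₀,θ₁) = F̂_j(θ₁) + e^{−τ(1+1/θ₁)} Σ_{i≤j} (τ^i/i!)[F̂_{j−i}(θ₀) − F̂_{j−i}(θ₁)]

with F̂_j(θ) = θ^j/(θ+1)^{j+1}. Limiting cases (τ=0 → old equilibrium,
τ→∞ → new equilibrium, θ₁→∞ → Poisson(τ) ⊛ equilibrium(θ₀)) are verified
in tests; the large-θ₁ Poisson form is exposed for cross-checks and as
the `constrained` fitting mode.

Fitting minimizes SSD = Σ(obs_j − exp_j)² under 0 ≤ θ₀ ≤ θ₁, τ ≥ 0 with
bounded L-BFGS-B from six seeded starts (two deterministic — a
expansion-like and an equilibrium-like start — plus four random). The
reported τ is the fitted model crest, not the empirical mode. The SSD
p-value is a parametric bootstrap: samples are drawn from a coalescent
with the fitted instantaneous size change (rate multiplied by θ₁/θ₀ older
than t = τ/θ₁ on the 2N₁ timescale; θ₀ = 0 collapses all remaining
lineages there), refitted, and compared by (hits+1)/(B+1); B defaults to
1000 and pipeline runs use a smaller documented value (the refit is the
expensive step).

Clock cross-calibration: a reference marker's divergence between two
calibration taxa and a published rate range date their split
(t = divergence/rate; the fast rate gives the young bound); the target
marker's divergence across the same split yields its rate range; half the
divergence rate (changes accrue on both lineages), converted from %/Myr,
is the per-site per-year mutation rate. Expansion dating inverts
τ = 2μt with μ per sequence per generation (μ_site · L · generation
time); generation time defaults to 1 year (annual life cycle) and is a
parameter. The chain is pure arithmetic and is covered by exact
round-trip identities in the tests.

## Synthetic data

* Neutral sampler: explicit Kingman coalescent — exponential waiting
  times at rate C(j,2), mutations Poisson(θ/2·Δt) per lineage, E[S] =
  θ·a₁(n), E[π̂] = θ. A summaries-only path (S, π̂, k without sequences)
  backs the p-value and bootstrap loops; the sequence path maps
  infinite-sites mutations onto distinct uniformly drawn sites of an
  L-site locus (an error is raised in the pathological case of more
  mutations than sites).
* Star expansion: Poisson(τ/2) private mutations per lineage; pairwise
  differences ~ Poisson(τ) and a dominant central haplotype — the extreme
  sudden-expansion signature.
* Island model: structured coalescent, within-deme pair coalescence at
  rate 1 (time in 2N units per deme), migration at rate M/2 per lineage
  with M = 2Nm; for d demes the expected fixation index is roughly
  1/(1 + 2Nm(d/(d−1))²), and the generator reproduces that band in tests.
* The `polycystum-like` preset emulates the regime of a low-diversity,
  recently expanded macroalga survey: 27 sampling sites × 7 samples of a
  379-bp locus under star expansion with τ = 0.06, chosen so the expected
  number of polymorphic sites (n·τ/2 ≈ 5.7) and haplotype count (≈ 5–7)
  sit in the observed few-haplotype regime. It emulates the *shape* of
  such data (star genealogy, singleton-dominated haplotype spectrum), not
  any particular dataset: there is no recombination, no rate
  heterogeneity, no sequencing error, and sampling sites are arbitrary
  labels without geography. Passing tests on these generators therefore
  validate the estimators under their own model assumptions, not the
  field realism of any conclusion.

## Problem sizes and numerical conventions

Monte-Carlo defaults are 10,000 permutations (AMOVA, Mantel) and 1000
simulations/bootstraps; the bundled tests and the acceptance script use
smaller, explicitly stated sizes (e.g. 2000 coalescent replicates for the
sampler calibration, 100 star-expansion replicates for τ recovery, 400
replicates × 100 simulations for p-value uniformity) — sizes at which the
checks are already decisive. All stochastic entry points take explicit
seeds and are bit-reproducible. Permutation and bootstrap p-values use
(hits+1)/(B+1) throughout; statistic comparisons in permutation counts
use a 1e-12 slack so exact ties count as hits. Undefined statistics
(D with S=0, Fs with k=1, Mantel with a constant triangle) are NaN with a
reason code rather than silently zero.

## Known limitations

* The parsimony-probability computation is a faithful re-derivation of
  the occupancy/coalescent model, but original-program equality is
  unverified; limits may differ by a step or two from TCS output.
* Fu's Fs p-values are simulated conditional on θ̂_π, not on S; for very
  small θ the null distribution is coarse.
* AMOVA treats haplotypes as haploid tokens; no diploid/genotypic AMOVA.
* The mismatch bootstrap refits with a reduced start set for speed; for
  pathological multimodal SSD surfaces the free fit can park θ₁ at its
  bound (the constrained mode is the robust alternative).
* No recombination, selection or sequencing-error models anywhere.
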