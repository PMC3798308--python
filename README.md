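# haplopop

Population-genetic analysis of multi-locus haplotype data, built for the
kind of shallow-structure phylogeography study common in marine organisms
(e.g. the brown macroalga *Sargassum*): a few hundred sequences per locus,
a handful of haplotypes, star-shaped genealogies and a recent-expansion
signal. The package takes per-locus alignments (FASTA) plus a
sample-to-population map (TSV) and runs the complete downstream workflow:

* **haplotype collapsing** and per-population frequency tables;
* **diversity indices** — haplotype diversity *h* = n/(n−1)(1 − Σp²) and
  nucleotide diversity π with their standard deviations;
* **neutrality tests** — Tajima's *D* and Fu's *Fs* (Ewens-distribution
  log-odds of the observed allele count, computed with a log-space Stirling
  recursion), with significance from neutral-coalescent simulation;
* **population structure** — pairwise Φ_ST, hierarchical AMOVA with
  permutation tests (Φ_ST, Φ_SC, Φ_CT), candidate-grouping ranking, and a
  Mantel test of isolation by distance;
* **statistical-parsimony haplotype networks** (TCS-style) with a
  95%-parsimony connection limit;
* **demographic history** — mismatch distributions, least-squares fitting
  of the Rogers–Harpending sudden-expansion model
  F_j(τ, θ₀, θ₁) with parametric-bootstrap SSD goodness of fit, molecular
  clock cross-calibration between markers, and expansion dating via
  τ = 2μt;
* **synthetic data** — seeded coalescent generators (neutral equilibrium,
  star expansion, sudden expansion, finite-island migration) that back the
  significance machinery and produce test fixtures.

## Worked example

Simulate a low-diversity expansion-regime dataset, run the full pipeline,
then date the expansion with a cross-calibrated clock:

```bash
haplopop simulate --scenario polycystum-like --seed 7 --out demo/cox3
haplopop mismatch --fasta demo/cox3.fasta --popmap demo/cox3.popmap.tsv \
    --out demo/fit.json --n-boot 100 --seed 7
haplopop date --ref-divergence 5.67 --clock-low 0.08 --clock-high 0.12 \
    --target-divergence 14.7 --tau 0.484 --sites 379 --out demo/dating.json
```

The mismatch command prints the fitted expansion parameters, e.g.

```
tau=0.0542 theta0=0.0000 theta1=48.05 SSD=0.00000 p=0.5743 -> demo/fit.json
```

(τ is the fitted crest of the pairwise-difference distribution; a large
SSD p-value means the sudden-expansion model is not rejected). The dating
command chains the clock calibration — reference divergence 5.67% at
0.08–0.12 %/Myr dates the calibration split at 47.25–70.875 Myr; a target
divergence of 14.7% then implies 0.207–0.311 %/Myr, i.e. a mutation rate
of 1.04–1.56 × 10⁻⁹ /site/yr — and prints

```
expansion dated 0.41-0.62 Mya -> demo/dating.json
```

meaning the τ = 0.484 expansion falls in the middle Pleistocene.

A whole multi-locus study (diversity tables, Φ_ST matrices, AMOVA over
candidate groupings, network exports, mismatch fits, dating) runs from one
YAML config with `haplopop run-all --config config.yaml`; outputs are
byte-identical given the same config and seeds.

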