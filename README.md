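# kirpop

Population analysis of KIR (killer-cell immunoglobulin-like receptor)
gene content. The KIR cluster on 19q13.4 varies between individuals in
which genes are present at all; routine typing therefore yields, per
individual, a presence/absence vector over 16 loci. `kirpop` turns
such tables — and the HLA class I typings that define KIR ligands —
into the statistics immunogenetics studies report, and provides a
study-shaped synthetic cohort generator so every stage is testable
without access to individual-level data.

It is aimed at immunogenetics and transplant-immunology groups
analysing KIR gene-content cohorts and comparing them across
populations.

## What it computes

**Gene and genotype frequencies.** Carrier frequencies CF by direct
count; gene frequencies by Bernstein's estimator under Hardy-Weinberg
equilibrium,

    GF = 1 − √(1 − CF),

with Wald confidence intervals GF ± z·√(GF(1−GF)/2N) over 2N gene
copies; AA/Bx genotype labels; AFND-style genotype IDs from a local
catalogue with NPR (not previously reported) labelling of novel
contents; KIR2DS4 full-length/deleted variant tables.

**Haplotype inference.** Given named reference haplotypes (cen~tel
motifs, Vierra-Green nomenclature), `HaplotypeFrequencyModel`
enumerates the reference pairs whose gene union matches each
individual and fits haplotype frequencies by EM on the HWE multinomial
likelihood P(g) = Σ c·f(h₁)f(h₂). Individuals explained by no pair
but containing a single reference contribute one chromosome, so
explained/residual mass is accounted per chromosome.

**KIR-HLA ligand combinations.** Allele-group-level classification of
HLA typings into C1/C2, Bw4, Bw4-80I, A3/A11; four-cell present/absent
tables per KIR-ligand pair; inhibitory-pair multiplicity
distributions.

**Population comparison.** Nei (1972) standard genetic distance on
carrier-frequency tables, neighbor-joining dendrograms (Newick),
correlation-biplot PCA, and Euclidean hierarchical clustering for
heatmaps.

## Worked example

```python
from kirpop import simulate_kir_population, HaplotypeFrequencyModel
from kirpop.simulate import SimulationConfig

profiles, _ = simulate_kir_population(SimulationConfig(seed=42))
res = HaplotypeFrequencyModel(profiles).fit()
print(res.summary())
```

```
HWE haplotype frequency estimates (EM)
  individuals: 161  chromosomes: 322
  iterations: 41  converged: True
  log-likelihood: -373.6004
  resolved both/one/none: 139/22/0
  explained chromosome mass: 93.17%  residual: 6.83%

  haplotype               count   percent
  cA01~tA01                 132    40.882
  cA01~tB01 2DS5             61    18.872
  cB02~tA01                  42    13.086
  cB02~tB01                  30     9.232
  cA01~tB05                  19     5.774
  cB01~tA01 2DS3             11     3.486
  cB01~tB01 2DS3              6     1.836 *
  * fewer than 8 chromosomes; interpret with caution
```

The cohort was simulated under HWE from the seven common haplotype
frequencies of the studied admixed population (41.6% cA01~tA01, ...)
plus an unmodelled rare haplotype at 7.8%; the fit recovers the
generating frequencies within sampling error: e.g. cA01~tA01 estimated
at 40.9% (132/322 chromosomes) against a generating 41.6%, and the
residual 6.8% estimates the rare mass. The `count` column is the
estimated number of chromosomes among 2N = 322; rows under eight
chromosomes are flagged as below the usual reporting threshold.

The same pipeline runs from the shell:

```
kirpop simulate --out bundle --seed 42
kirpop frequencies --genotypes bundle/genotypes.csv --catalog bundle/genotype_catalog.csv --out out_freq
kirpop haplotypes  --genotypes bundle/genotypes.csv --out out_hap
kirpop ligands     --genotypes bundle/genotypes.csv --hla bundle/hla.csv --out out_lig
kirpop compare     --freqs bundle/population_frequencies.csv --out out_cmp
```

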