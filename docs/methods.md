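# Methods

## The observation model

KIR gene-content typing (PCR-SSO/SSP) reports, per individual, presence
or absence of each of 16 loci: 14 expressed genes and the pseudogenes
KIR2DP1/KIR3DP1. Four framework loci (3DL3, 3DP1, 2DL4, 3DL2) sit on
essentially every haplotype; seven loci (2DL2, 2DL5, 2DS1, 2DS2, 2DS3,
2DS5, 3DS1) occur only on group-B haplotypes, so an individual carrying
none of them is labelled AA and anyone else Bx (A/B vs B/B cannot be
separated from gene content).

Because typing is presence/absence, an individual's data is the union
of the gene contents of two haplotypes. All downstream inference in
this package is built on that single fact.

## Carrier and gene frequencies

The carrier frequency CF of a locus is the direct-count fraction of
positive individuals. Under Hardy-Weinberg equilibrium (HWE),
non-carriers are homozygous for locus absence, so the locus-level gene
frequency follows Bernstein's estimator GF = 1 − √(1 − CF). The
confidence interval is the Wald interval GF ± z(level)·√(GF(1−GF)/2N)
with 2N gene copies as the denominator and z from the normal quantile
(1.96 at the default level 0.95), clipped to [0, 1]. Fixed loci
(CF = 1) get a degenerate interval. The Wald form is used deliberately
(it is what published KIR tables print); exact Clopper-Pearson
intervals are out of scope.

For the KIR2DS4 full-length/22-bp-deleted variant table, the Bernstein
conversion is applied to each zygosity category's cohort-wide carrier
rate in turn. This mirrors the arithmetic of published cohort tables
and is *not* a standard allele-frequency estimator; it is kept for
comparability and documented as such.

## Haplotype inference

`HaplotypeFrequencyModel` estimates haplotype frequencies from gene
content given a list of named reference haplotypes (cen~tel motif
patterns in the Vierra-Green nomenclature). Reference entries must
satisfy four structural rules: (I) framework genes always present;
(II) 2DL5 implies 2DS3 and/or 2DS5; (III) 2DL2 and 2DL3 mutually
exclusive per haplotype; (IV) 2DS4 implies 3DL1. Matching is on total
gene content; the centromeric/telomeric placement of the duplicated
2DS3/2DS5 locus is metadata only.

For each individual the model enumerates every unordered reference
pair whose union equals the observed content (verified in tests
against a brute-force scan). The likelihood is the standard HWE
multinomial: P(genotype) = Σ over compatible pairs of c·f(h1)f(h2),
c = 2 for heterozygous pairs. Individuals with no compatible pair but
with at least one single reference contained in their profile
contribute one observed chromosome (the partner stays unexplained);
the E-step weights their candidate haplotypes by current frequency.
Individuals matching nothing contribute nothing. Reported frequencies
are fractions of all 2N chromosomes, so Σf + residual = 1 with the
residual the unassigned chromosome mass — the convention that makes a
"% of haplotype variation explained" statement well defined. This
chromosome-level accounting, rather than dropping half-resolved
individuals outright, is also what makes simulation-based parameter
recovery unbiased.

EM details: uniform initialisation (deterministic; the landscape is
well behaved at this scale, and no random restarts are used),
convergence when the largest frequency change drops below `tol`
(default 1e-8) or after `max_iter` (default 1000) iterations; the
log-likelihood trace is retained and is nondecreasing by construction
(asserted in tests). Estimated haplotypes with fewer than eight
chromosomes are flagged below the usual reporting threshold for
gene-content inference.

The shipped reference file carries the seven most frequent cen~tel
haplotypes. Motif contents follow the standard definitions
(cA01 = 3DL3-2DL3-2DP1-2DL1-3DP1; cB01 = 3DL3-2DS2-2DL2-2DL5-2DS3/5-
2DP1-2DL1-3DP1; cB02 = 3DL3-2DS2-2DL2-3DP1; tA01 = 2DL4-3DL1-2DS4-3DL2;
tB01 = 2DL4-3DS1-2DL5-2DS5/3-2DS1-3DL2). The exact content of tB05 was
not recoverable from available sources; this package uses
{2DL4, 3DS1, 2DL5, 2DS3, 2DS1, 3DL2}, chosen so that no reference's
gene set nests inside another telomeric-B reference, and the file is
user-replaceable for anyone holding the authoritative definition.

## KIR-HLA ligand combinations

HLA class I epitopes are assigned at allele-group (two-digit)
resolution through an editable CSV lookup: the HLA-C C1/C2 dichotomy,
Bw4 on HLA-B plus A*23/24/32, the Bw4-80I subset (restricted to B-locus
groups in the shipped lookup; B-groups mixing 80I/80T alleles are
resolved by majority allele), and A3/A11. Groups whose epitope varies
at allele level are a known limit of two-digit typing — the lookup is
data, not code, and should be reviewed before fine-grained use.

Pair tables count the four exhaustive cells (KIR present/absent ×
ligand present/absent) per combination; 2DS4F pairs require at least
one full-length 2DS4 copy (zygosity FF or FD). Individuals without
HLA-C typing carry `None` C-flags and are excluded from C-dependent
pairs with a logged count. The inhibitory multiplicity table assigns
each individual the exact subset of the four canonical inhibitory
pairs (2DL1+C2, 2DL2/3+C1, 3DL1+Bw4, 3DL2+A3/11) and groups by subset
size.

## Population comparison

Populations are compared on per-locus *carrier* frequencies (the scale
published registries report); a Bernstein-converted variant is
available for sensitivity analysis. Each locus is treated as biallelic
(p, 1−p). Nei's (1972) standard distance D = −ln(J_xy/√(J_x·J_y)) is
summed per locus; a zero identity reports +∞ explicitly. Neighbor
joining is the Saitou-Nei algorithm with deterministic tie-breaking
(lowest index pair) and negative branch lengths clamped to zero with
the deficit moved to the sister branch — a convention that additive
inputs never trigger, and tests require exact (1e-9) recovery of
additive matrices. PCA is a plain SVD of the column-centred (and, by
default, unit-scaled — a correlation biplot) matrix, with each
component's sign fixed so its largest-magnitude loading is positive;
zero-variance genes are dropped with a warning under standardisation.
Hierarchical clustering (scipy, complete linkage on Euclidean
distance by default) returns merge heights and leaf order for heatmap
rendering. Cohorts lacking pseudogene typing are handled by
restricting the shared gene set (14 loci), never by imputation.

## Synthetic cohorts

`SimulationConfig` defaults encode the studied cohort: N = 161
individuals; the seven reference haplotypes at their published
frequencies (41.615, 16.46, 10.87, 9.938, 5.901, 4.969, 2.484%), with
the remaining 7.76% on a synthetic "RARE" haplotype; ligand carriage
rates C1 = 0.87, Bw4 = 0.87, C2 = 0.5839, A3/A11 = 0.2236,
Bw4-80I = 0.374, C*16 = 0.0807; and FF/FD/DD proportions 0.427/0.3466/
0.2264 among 2DS4 carriers (the published cohort-wide 39.8/32.3/21.1%
renormalised over 93.2% carriage — the observed proportions are not
HWE-consistent with a single allele fraction, hence an explicit
categorical rather than an allele-frequency parameter).

Each individual draws two haplotypes independently (HWE) and reports
the gene union. The RARE content — framework plus both 3DL1 and 3DS1,
a duplication-like pattern — was chosen by exhaustive search so that
no union involving RARE coincides with any reference-pair union:
RARE carriers become half-resolved or unresolved exactly as intended,
at rates (≈ 85/14/1%) close to the published resolution statistics.

Ligand flags are independent Bernoulli draws (KIR-ligand independence
is assumed; a joint sampler can replace the two calls for correlated
designs), with structural consistency enforced: Bw4-80I as a sub-event
of B-locus Bw4, C*16 as a sub-event of C1, A3/A11 carriers split
25:9:1 into A3-only/A11-only/both, and at most two HLA-A-slot epitopes
per individual so the flag set is realisable as a two-allele typing.
The fixture bundle renders flags as representative allele groups
(C1 → C*07, C2 → C*04, 80I → B*51, ...); individuals with neither C1
nor C2 are written untyped at HLA-C, exercising the missing-typing
path. One seeded generator stream drives all draws, in order:
haplotypes (with zygosities interleaved), then ligands, then the
jittered comparison populations.

What the generator does *not* emulate: allelic diversity and copy
number, linkage between cen and tel motifs beyond the haplotype list,
KIR-HLA dependence, and population structure/admixture. Passing
recovery tests therefore demonstrate correctness of the inference
under its own assumptions, not robustness to their violation in real
cohorts.

## Numerical and edge-case choices

- Presence tokens accepted: 0/1, NEG/POS (case-insensitive); anything
  else is a hard error with row/column context.
- Framework-gene absence is a warning finding, never an exception.
- Published-table comparisons in tests use a tolerance of one unit in
  the last printed digit: the source tables carry occasional last-digit
  rounding inconsistencies (e.g. a CI bound computing 82.25 but printed
  82.2, a gene frequency computing 31.75 but printed 31.8), and
  anything tighter would encode those artifacts.
- Genotype-table and haplotype-table ordering: descending count, ties
  by ID/name ascending; NPR labels sort after numeric IDs.
- EM with every individual incompatible raises; a single compatible
  individual is enough to fit.
- Nei distance of identical populations is exactly 0 even at fixed
  loci; D(x,x) never hits the log singularity.

## Problem sizes

Default test and acceptance runs use cohorts of 161-2,000 individuals
(20,000 for rate-convergence checks), 500 random profiles for the
enumeration oracle and 100 random 5-8-taxon trees for NJ recovery;
the full suite completes in a few seconds.
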