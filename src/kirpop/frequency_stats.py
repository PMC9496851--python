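"""Carrier frequencies, Bernstein gene frequencies and Wald intervals.

Presence/absence typing yields carrier frequencies (CF): the fraction of
individuals in whom a locus is detected, regardless of copy number.
Under Hardy-Weinberg equilibrium the locus-level gene frequency follows
Bernstein's estimator

    GF = 1 - sqrt(1 - CF),

since non-carriers are homozygous for gene absence, CF = 1 - (1 - GF)^2.
The confidence interval is the Wald interval on GF with the normal
quantile z(level) and the number of gene copies 2N as the denominator:

    GF +/- z * sqrt(GF (1 - GF) / (2 N)),

clipped to [0, 1].  For framework loci (CF = GF = 1) the interval is
degenerate at 100%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .panel import DEFAULT_PANEL, GenePanel
from .genotype_io import DS4_ZYGOSITIES


@dataclass(frozen=True)
class FrequencyRecord:
    """Per-gene carrier count and derived frequencies (all as fractions)."""

    gene: str
    carriers: int
    n: int
    cf: float
    gf: float
    ci_low: float
    ci_high: float
    level: float

    def __post_init__(self) -> None:
        if not 0 <= self.carriers <= self.n:
            raise ValueError("carrier count must lie in [0, N]")
        if not (0.0 <= self.gf <= self.cf <= 1.0):
            raise ValueError("frequencies must satisfy 0 <= GF <= CF <= 1")
        if not (self.ci_low <= self.gf <= self.ci_high):
            raise ValueError("CI must bracket GF")


def carrier_frequency(k: int, n: int) -> float:
    """Fraction of carriers k/N by direct count."""
    if n <= 0:
        raise ValueError("cohort size N must be positive")
    if not 0 <= k <= n:
        raise ValueError(f"carrier count {k} outside [0, {n}]")
    return k / n


def bernstein_gene_frequency(cf: float) -> float:
    """GF = 1 - sqrt(1 - CF)."""
    if not 0.0 <= cf <= 1.0:
        raise ValueError(f"carrier frequency {cf} outside [0, 1]")
    return 1.0 - math.sqrt(1.0 - cf)


def gene_frequency_ci(
    gf: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """Wald interval for GF over 2N gene copies, clipped to [0, 1]."""
    if not 0.0 <= gf <= 1.0:
        raise ValueError(f"gene frequency {gf} outside [0, 1]")
    if n <= 0:
        raise ValueError("cohort size N must be positive")
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level {level} outside (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(gf * (1.0 - gf) / (2 * n))
    return (max(0.0, gf - half), min(1.0, gf + half))


def ds4_variant_frequencies(profiles) -> pd.DataFrame:
    """Tabulate KIR2DS4 full-length/deleted zygosity categories.

    carrier_pct is the category count over the whole cohort; the
    Bernstein conversion is applied to each category's carrier rate in
    turn, mirroring the study's arithmetic (not a standard per-allele
    estimator; kept for faithfulness to the published table).
    Unknown-zygosity individuals stay in the denominator but count in no
    category.
    """
    n = len(profiles)
    if n == 0:
        raise ValueError("need at least one profile")
    rows = []
    for cat in DS4_ZYGOSITIES:
        k = sum(
            1
            for p in profiles
            if p.has("2DS4") and p.ds4_zygosity == cat
        )
        cf = k / n
        rows.append(
            {
                "category": cat,
                "n": k,
                "carrier_pct": cf * 100.0,
                "bernstein_pct": bernstein_gene_frequency(cf) * 100.0,
            }
        )
    return pd.DataFrame(rows)


def population_summary(
    profiles,
    panel: GenePanel = DEFAULT_PANEL,
    level: float = 0.95,
) -> list[FrequencyRecord]:
    """Per-gene direct counts with CF, GF and the Wald interval."""
    if not profiles:
        raise ValueError("need at least one profile")
    n = len(profiles)
    records = []
    for gene in panel.genes:
        k = sum(1 for p in profiles if p.has(gene))
        cf = carrier_frequency(k, n)
        gf = bernstein_gene_frequency(cf)
        lo, hi = gene_frequency_ci(gf, n, level)
        records.append(FrequencyRecord(gene, k, n, cf, gf, lo, hi, level))
    return records


def summary_to_frame(records) -> pd.DataFrame:
    """Tidy long-format view of :func:`population_summary` (percent scale)."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "carriers": [r.carriers for r in records],
            "n": [r.n for r in records],
            "carrier_pct": [r.cf * 100.0 for r in records],
            "gene_freq_pct": [r.gf * 100.0 for r in records],
            "ci_low_pct": [r.ci_low * 100.0 for r in records],
            "ci_high_pct": [r.ci_high * 100.0 for r in records],
        }
    )


def summary_to_wide(records) -> pd.DataFrame:
    """Genes-as-columns view with the four statistic rows of a published
    gene-frequency table (direct count, CF%, GF%, CI%)."""
    df = summary_to_frame(records).set_index("gene")
    wide = pd.DataFrame(
        {
            gene: {
                "direct_count": df.loc[gene, "carriers"],
                "carrier_pct": df.loc[gene, "carrier_pct"],
                "gene_freq_pct": df.loc[gene, "gene_freq_pct"],
                "ci_pct": f"{df.loc[gene, 'ci_low_pct']:.1f}-"
                f"{df.loc[gene, 'ci_high_pct']:.1f}",
            }
            for gene in df.index
        }
    )
    return wide
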