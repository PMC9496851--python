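"""The KIR gene-content panel.

Presence/absence typing covers 14 expressed loci and the two pseudogenes
(KIR2DP1, KIR3DP1).  Four loci -- KIR3DL3, KIR3DP1, KIR2DL4 and KIR3DL2 --
are *framework* genes delimiting the centromeric and telomeric halves of
the cluster and are carried on essentially every haplotype.  A second
subset of loci occurs only on group-B haplotypes; an individual carrying
none of them has the canonical AA genotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Panel loci in conventional order (short names, without the "KIR" prefix).
GENE_ORDER: tuple[str, ...] = (
    "2DL1", "2DL2", "2DL3", "2DL4", "2DL5",
    "2DS1", "2DS2", "2DS3", "2DS4", "2DS5",
    "3DL1", "3DL2", "3DL3", "3DS1", "2DP1", "3DP1",
)

FRAMEWORK_GENES: frozenset[str] = frozenset({"3DL3", "3DP1", "2DL4", "3DL2"})

#: Loci found only on group-B haplotypes.
B_SPECIFIC_GENES: frozenset[str] = frozenset(
    {"2DL2", "2DL5", "2DS1", "2DS2", "2DS3", "2DS5", "3DS1"}
)


def normalize_gene_name(name: str) -> str:
    """Map a column header or label to the panel's short locus name.

    Tolerates the "KIR" prefix, surrounding whitespace and case
    (``"kir2dl1"`` -> ``"2DL1"``).
    """
    short = name.strip().upper()
    if short.startswith("KIR"):
        short = short[3:]
    return short


@dataclass(frozen=True)
class GenePanel:
    """An ordered set of KIR loci with its framework and B-specific subsets."""

    genes: tuple[str, ...] = GENE_ORDER
    framework: frozenset[str] = FRAMEWORK_GENES
    b_specific: frozenset[str] = B_SPECIFIC_GENES

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("panel gene names must be unique")
        gene_set = set(self.genes)
        if not self.framework <= gene_set:
            raise ValueError("framework genes must be a subset of the panel")
        if not self.b_specific <= gene_set:
            raise ValueError("B-specific genes must be a subset of the panel")
        if self.framework & self.b_specific:
            raise ValueError("framework and B-specific subsets must be disjoint")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def restrict(self, genes) -> "GenePanel":
        """Panel restricted to ``genes`` (e.g. the 14-locus panel without
        the pseudogenes used for Amerindian comparisons)."""
        keep = {normalize_gene_name(g) for g in genes}
        missing = keep - set(self.genes)
        if missing:
            raise ValueError(f"genes not in panel: {sorted(missing)}")
        return GenePanel(
            genes=tuple(g for g in self.genes if g in keep),
            framework=frozenset(self.framework & keep),
            b_specific=frozenset(self.b_specific & keep),
        )


#: The default 16-locus presence/absence panel.
DEFAULT_PANEL = GenePanel()
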