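"""Reading, validating and cataloguing KIR gene-content genotypes.

A genotype here is the per-individual presence/absence vector over the
panel loci, optionally annotated with the KIR2DS4 full-length/deleted
zygosity (the 22-bp exon-5 deletion produces a non-expressed variant).
Genotype identifiers follow the AFND convention of numbering distinct
gene-content patterns; patterns absent from the local catalogue are
labelled NPR1, NPR2, ... (not previously reported) in first-encounter
order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .panel import DEFAULT_PANEL, GenePanel, normalize_gene_name

DS4_ZYGOSITIES = ("FF", "FD", "DD")

_TRUE_TOKENS = {"1", "POS", "TRUE", "T"}
_FALSE_TOKENS = {"0", "NEG", "FALSE", "F"}


@dataclass(frozen=True)
class GenotypeProfile:
    """One individual's KIR gene-content, plus optional 2DS4 zygosity."""

    individual_id: str
    present: dict[str, bool]
    ds4_zygosity: str | None = None

    def __post_init__(self) -> None:
        if self.ds4_zygosity is not None and self.ds4_zygosity not in DS4_ZYGOSITIES:
            raise ValueError(
                f"ds4_zygosity must be one of {DS4_ZYGOSITIES} or None, "
                f"got {self.ds4_zygosity!r}"
            )

    @property
    def present_set(self) -> frozenset[str]:
        return frozenset(g for g, p in self.present.items() if p)

    def has(self, gene: str) -> bool:
        return self.present.get(gene, False)


@dataclass(frozen=True)
class ValidationFinding:
    individual_id: str
    gene: str
    rule: str
    message: str


def _parse_presence(token, row_label, column) -> bool:
    text = str(token).strip().upper()
    if text in _TRUE_TOKENS:
        return True
    if text in _FALSE_TOKENS:
        return False
    raise ValueError(
        f"unparseable presence value {token!r} at row {row_label}, column {column}"
    )


def read_genotype_table(
    path,
    panel: GenePanel = DEFAULT_PANEL,
    id_column: str = "individual_id",
) -> list[GenotypeProfile]:
    """Read a delimited genotype table (one row per individual).

    The header must name the ID column and one column per panel gene;
    gene headers are matched tolerantly ("KIR2DL1", "2dl1", ...).
    Presence is encoded as 1/0 or POS/NEG (case-insensitive).  An
    optional ``ds4_zygosity`` column carries FF/FD/DD (anything else,
    including blanks, is treated as unknown).
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    colmap: dict[str, str] = {}
    for col in df.columns:
        short = normalize_gene_name(col)
        if short in panel.genes:
            colmap[short] = col
    missing = [g for g in panel.genes if g not in colmap]
    if missing:
        raise ValueError(
            f"genotype table {path} is missing panel gene column(s): "
            + ", ".join("KIR" + g for g in missing)
        )
    if id_column not in df.columns:
        raise ValueError(f"genotype table {path} lacks ID column {id_column!r}")

    ds4_col = next(
        (c for c in df.columns if c.strip().lower() == "ds4_zygosity"), None
    )

    profiles: list[GenotypeProfile] = []
    seen: set[str] = set()
    for idx, row in df.iterrows():
        iid = str(row[id_column]).strip()
        if iid in seen:
            raise ValueError(f"duplicate individual_id {iid!r} in {path}")
        seen.add(iid)
        present = {
            g: _parse_presence(row[colmap[g]], iid, colmap[g]) for g in panel.genes
        }
        zyg = None
        if ds4_col is not None:
            token = str(row[ds4_col]).strip().upper()
            if token in DS4_ZYGOSITIES:
                zyg = token
        profiles.append(GenotypeProfile(iid, present, zyg))
    return profiles


def validate_profiles(
    profiles, panel: GenePanel = DEFAULT_PANEL
) -> list[ValidationFinding]:
    """Flag framework-gene absences.

    Framework genes are present in almost all individuals, so absence is
    reported as a warning finding rather than raised as an error: real
    cohorts may legitimately contain deletion haplotypes.
    """
    findings = []
    for profile in profiles:
        for gene in panel.genes:
            if gene in panel.framework and not profile.has(gene):
                findings.append(
                    ValidationFinding(
                        profile.individual_id,
                        gene,
                        "framework_gene_absent",
                        f"framework gene KIR{gene} absent in "
                        f"{profile.individual_id}",
                    )
                )
    return findings


def classify_ab(profile: GenotypeProfile, panel: GenePanel = DEFAULT_PANEL) -> str:
    """AA if no B-specific gene is present, otherwise Bx.

    Gene content alone cannot separate A/B heterozygotes from B/B
    homozygotes, hence the two-way AA/Bx labelling.
    """
    return "AA" if not (profile.present_set & panel.b_specific) else "Bx"


class GenotypeCatalog:
    """Mapping from genotype ID to gene-content set.

    The shipped default is a partial local snapshot (no network lookup of
    AFND); it is user-replaceable via :meth:`from_csv`.
    """

    def __init__(self, entries: dict[str, frozenset[str]], provenance: str = ""):
        self.entries = dict(entries)
        self.provenance = provenance
        contents: dict[frozenset[str], str] = {}
        for gid, genes in self.entries.items():
            if genes in contents:
                raise ValueError(
                    f"catalog integrity error: IDs {contents[genes]!r} and "
                    f"{gid!r} share identical gene content"
                )
            contents[genes] = gid
        self._by_content = contents

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, genes: frozenset[str]) -> str | None:
        return self._by_content.get(frozenset(genes))

    def insert(self, genotype_id: str, genes) -> None:
        genes = frozenset(genes)
        if genotype_id in self.entries:
            raise ValueError(f"duplicate genotype ID {genotype_id!r}")
        if genes in self._by_content:
            raise ValueError(
                f"catalog integrity error: content already present under ID "
                f"{self._by_content[genes]!r}"
            )
        self.entries[genotype_id] = genes
        self._by_content[genes] = genotype_id

    @classmethod
    def from_csv(cls, path, panel: GenePanel = DEFAULT_PANEL) -> "GenotypeCatalog":
        df = pd.read_csv(path, dtype=str)
        if "genotype_id" not in df.columns:
            raise ValueError(f"catalog {path} lacks a genotype_id column")
        colmap = {
            normalize_gene_name(c): c
            for c in df.columns
            if normalize_gene_name(c) in panel.genes
        }
        entries = {}
        for _, row in df.iterrows():
            gid = str(row["genotype_id"]).strip()
            genes = frozenset(
                g
                for g, col in colmap.items()
                if _parse_presence(row[col], gid, col)
            )
            if gid in entries:
                raise ValueError(f"duplicate genotype ID {gid!r} in {path}")
            entries[gid] = genes
        return cls(entries, provenance=str(path))

    def to_csv(self, path, panel: GenePanel = DEFAULT_PANEL) -> None:
        rows = []
        for gid, genes in self.entries.items():
            row = {"genotype_id": gid}
            row.update({g: int(g in genes) for g in panel.genes})
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)


class GenotypeMatcher:
    """Assign catalogue IDs, labelling novel contents NPR1, NPR2, ...

    NPR numbering is per-matcher (per run) in first-encounter order and
    stable: the same content always receives the same label.
    """

    def __init__(self, catalog: GenotypeCatalog):
        self.catalog = catalog
        self._npr: dict[frozenset[str], str] = {}

    def match(self, profile: GenotypeProfile) -> str:
        content = profile.present_set
        gid = self.catalog.lookup(content)
        if gid is not None:
            return gid
        if content not in self._npr:
            self._npr[content] = f"NPR{len(self._npr) + 1}"
        return self._npr[content]


def match_genotype_id(profile: GenotypeProfile, catalog: GenotypeCatalog) -> str:
    """Single-profile convenience wrapper around :class:`GenotypeMatcher`."""
    return GenotypeMatcher(catalog).match(profile)


def _genotype_sort_key(gid: str):
    # numeric IDs before NPR labels, each ascending
    if gid.startswith("NPR"):
        return (1, int(gid[3:]) if gid[3:].isdigit() else 0, gid)
    return (0, int(gid) if gid.isdigit() else 0, gid)


def genotype_frequency_table(
    profiles,
    catalog: GenotypeCatalog,
    panel: GenePanel = DEFAULT_PANEL,
) -> pd.DataFrame:
    """Group individuals by identical gene content and tabulate.

    Returns columns genotype_id, ab, n_loci, n, percent, sorted by
    descending count with ties broken by genotype ID ascending.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    matcher = GenotypeMatcher(catalog)
    counts: dict[str, dict] = {}
    total = len(profiles)
    for profile in profiles:
        gid = matcher.match(profile)
        if gid not in counts:
            counts[gid] = {
                "genotype_id": gid,
                "ab": classify_ab(profile, panel),
                "n_loci": len(profile.present_set),
                "n": 0,
            }
        counts[gid]["n"] += 1
    rows = sorted(
        counts.values(),
        key=lambda r: (-r["n"], _genotype_sort_key(r["genotype_id"])),
    )
    df = pd.DataFrame(rows)
    df["percent"] = df["n"] / total * 100.0
    return df
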