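"""HLA class I ligand classification and KIR-HLA combination tables.

KIR receptors recognise epitopes of classical HLA class I molecules:
the HLA-C dichotomy C1/C2 (position 80 asparagine vs lysine), the Bw4
motif of HLA-B (and A*23/24/32), its 80-isoleucine subset Bw4-80I, and
the A3/A11 epitope of HLA-A.  Classification here operates at allele-
group (two-digit) resolution through an editable lookup table shipped
as data: groups mixing epitope-positive and -negative alleles are
resolved in favour of the majority allele, so expert review of the
lookup is advised for fine-grained work.  In this lookup Bw4-80I is
restricted to HLA-B groups.

Individuals without HLA-C typing get ``None`` for the C-dependent flags
and are excluded (with a logged count) from C-dependent pair tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

EPITOPES = ("C1", "C2", "Bw4", "Bw4-80I", "A3", "A11", "C16")


@dataclass(frozen=True)
class LigandProfile:
    """Per-individual KIR-ligand carriage flags.

    Flags are booleans, or ``None`` when the underlying locus was not
    typed (missing HLA-C).
    """

    individual_id: str
    c1: bool | None = False
    c2: bool | None = False
    bw4: bool = False
    bw4_80i: bool = False
    bw4_from_a: bool = False
    bw4_from_b: bool = False
    a3: bool = False
    a11: bool = False
    c16: bool | None = False

    def __post_init__(self) -> None:
        if self.bw4_80i and not self.bw4:
            raise ValueError("Bw4-80I implies Bw4")
        if self.bw4 and not (self.bw4_from_a or self.bw4_from_b):
            raise ValueError("Bw4 must have an A- or B-locus provenance")

    def flag(self, name: str) -> bool | None:
        """Resolve a flag by name; "A3/A11" is the union of A3 and A11."""
        if name == "A3/A11":
            a, b = self.a3, self.a11
            if a or b:
                return True
            return None if (a is None or b is None) else False
        attr = {
            "C1": "c1",
            "C2": "c2",
            "Bw4": "bw4",
            "Bw4-80I": "bw4_80i",
            "Bw4(HLA-A)": "bw4_from_a",
            "Bw4(HLA-B)": "bw4_from_b",
            "A3": "a3",
            "A11": "a11",
            "C16": "c16",
        }[name]
        return getattr(self, attr)


class LigandLookup:
    """Allele-group -> epitope-set mapping."""

    def __init__(self, table: dict[str, frozenset[str]]):
        self.table = dict(table)
        for group, epis in self.table.items():
            unknown = epis - set(EPITOPES)
            if unknown:
                raise ValueError(f"{group}: unknown epitopes {sorted(unknown)}")
            if group.startswith("C*") and len(epis & {"C1", "C2"}) != 1:
                raise ValueError(
                    f"HLA-C group {group} must map to exactly one of C1/C2"
                )
            if "Bw4-80I" in epis and "Bw4" not in epis:
                raise ValueError(f"{group}: Bw4-80I requires Bw4")
            if {"A3", "A11"} <= epis:
                raise ValueError(f"{group}: A3 and A11 are disjoint epitopes")

    @classmethod
    def from_csv(cls, path) -> "LigandLookup":
        df = pd.read_csv(path, dtype=str)
        table = {}
        for _, row in df.iterrows():
            group = str(row["allele_group"]).strip()
            raw = row.get("epitopes")
            epis = (
                frozenset(e.strip() for e in str(raw).split(";") if e.strip())
                if pd.notna(raw)
                else frozenset()
            )
            table[group] = epis
        return cls(table)

    def get(self, allele_group: str) -> frozenset[str] | None:
        return self.table.get(allele_group.strip().upper())


def default_ligand_lookup() -> LigandLookup:
    src = resources.files("kirpop").joinpath("data/hla_ligand_groups.csv")
    with resources.as_file(src) as path:
        return LigandLookup.from_csv(path)


def classify_ligands(
    individual_id: str,
    alleles,
    lookup: LigandLookup,
    c_typed: bool = True,
) -> tuple[LigandProfile, list[str]]:
    """Union the epitopes of an individual's allele groups into flags.

    ``alleles`` are "locus*group" strings (e.g. "C*04").  Unknown groups
    yield a warning and are ignored.  With ``c_typed=False`` (or when no
    C-locus allele appears among typed loci) the C-dependent flags are
    ``None``.
    """
    warnings = []
    flags = {e: False for e in EPITOPES}
    bw4_from_a = bw4_from_b = False
    saw_c = False
    for allele in alleles:
        allele = str(allele).strip()
        if not allele:
            continue
        epis = lookup.get(allele)
        if epis is None:
            warnings.append(
                f"{individual_id}: allele group {allele!r} not in lookup; ignored"
            )
            continue
        if allele.upper().startswith("C*"):
            saw_c = True
        for e in epis:
            flags[e] = True
        if "Bw4" in epis:
            if allele.upper().startswith("A*"):
                bw4_from_a = True
            else:
                bw4_from_b = True
    c_known = c_typed and saw_c
    profile = LigandProfile(
        individual_id,
        c1=flags["C1"] if c_known else None,
        c2=flags["C2"] if c_known else None,
        bw4=flags["Bw4"],
        bw4_80i=flags["Bw4-80I"],
        bw4_from_a=bw4_from_a,
        bw4_from_b=bw4_from_b,
        a3=flags["A3"],
        a11=flags["A11"],
        c16=flags["C16"] if c_known else None,
    )
    return profile, warnings


def read_hla_table(path, lookup: LigandLookup | None = None):
    """Read an HLA typing CSV (individual_id, A_1, A_2, B_1, B_2, C_1,
    C_2; allele-group strings, C columns optionally blank) into ligand
    profiles.  Returns (profiles, warnings)."""
    if lookup is None:
        lookup = default_ligand_lookup()
    df = pd.read_csv(path, dtype=str)
    if "individual_id" not in df.columns:
        raise ValueError(f"HLA table {path} lacks individual_id column")
    allele_cols = [c for c in df.columns if c != "individual_id"]
    profiles, warnings = [], []
    for _, row in df.iterrows():
        iid = str(row["individual_id"]).strip()
        alleles = [
            str(row[c]).strip()
            for c in allele_cols
            if pd.notna(row[c]) and str(row[c]).strip()
        ]
        profile, w = classify_ligands(iid, alleles, lookup)
        profiles.append(profile)
        warnings.extend(w)
    return profiles, warnings


@dataclass(frozen=True)
class PairDefinition:
    """A KIR-gene / HLA-ligand combination.

    ``kir_genes`` lists alternatives (any present counts, e.g. 2DL2/3);
    ``requires_full_2ds4`` demands at least one full-length 2DS4 copy
    (zygosity FF or FD).
    """

    name: str
    kir_genes: tuple[str, ...]
    ligand_flag: str
    kind: str  # "inhibition" | "activation"
    requires_full_2ds4: bool = False


DEFAULT_PAIRS: tuple[PairDefinition, ...] = (
    PairDefinition("2DL1/C2", ("2DL1",), "C2", "inhibition"),
    PairDefinition("2DL2/C1", ("2DL2",), "C1", "inhibition"),
    PairDefinition("2DL3/C1", ("2DL3",), "C1", "inhibition"),
    PairDefinition("3DL1/Bw4", ("3DL1",), "Bw4", "inhibition"),
    PairDefinition("3DL1/Bw4 (HLA-B)", ("3DL1",), "Bw4(HLA-B)", "inhibition"),
    PairDefinition("3DL1/Bw4 (HLA-A)", ("3DL1",), "Bw4(HLA-A)", "inhibition"),
    PairDefinition("3DL2/A3 A11", ("3DL2",), "A3/A11", "inhibition"),
    PairDefinition("3DL2/A3", ("3DL2",), "A3", "inhibition"),
    PairDefinition("3DL2/A11", ("3DL2",), "A11", "inhibition"),
    PairDefinition("2DS1/C2", ("2DS1",), "C2", "activation"),
    PairDefinition("2DS2/C1", ("2DS2",), "C1", "activation"),
    PairDefinition("2DS2/HLA-C*16", ("2DS2",), "C16", "activation"),
    PairDefinition("2DS2/A11", ("2DS2",), "A11", "activation"),
    PairDefinition("3DS1/Bw4-80I", ("3DS1",), "Bw4-80I", "activation"),
    PairDefinition(
        "2DS4F/A3 A11", ("2DS4",), "A3/A11", "activation", requires_full_2ds4=True
    ),
)

#: The four canonical inhibitory KIR-ligand pairs (2DL2/3 as one pair).
INHIBITORY_PAIRS: tuple[PairDefinition, ...] = (
    PairDefinition("2DL1+C2", ("2DL1",), "C2", "inhibition"),
    PairDefinition("2DL2/3+C1", ("2DL2", "2DL3"), "C1", "inhibition"),
    PairDefinition("3DL1+Bw4", ("3DL1",), "Bw4", "inhibition"),
    PairDefinition("3DL2+A3/11", ("3DL2",), "A3/A11", "inhibition"),
)


def _kir_present(profile, pair: PairDefinition) -> bool:
    if not any(profile.has(g) for g in pair.kir_genes):
        return False
    if pair.requires_full_2ds4:
        return profile.ds4_zygosity in ("FF", "FD")
    return True


def _join(profiles, ligand_profiles):
    ligands = {lp.individual_id: lp for lp in ligand_profiles}
    joined = []
    for p in profiles:
        lp = ligands.get(p.individual_id)
        if lp is None:
            raise ValueError(
                f"individual {p.individual_id!r} missing from the HLA table"
            )
        joined.append((p, lp))
    return joined


def kir_hla_pair_table(
    profiles, ligand_profiles, pairs=DEFAULT_PAIRS
) -> pd.DataFrame:
    """Four-cell (present/present ... absent/absent) table per pair.

    Cells partition the individuals with a known ligand status for that
    pair; individuals with unknown status (untyped HLA-C) are excluded
    from the affected pair and counted in ``n_excluded``.
    """
    joined = _join(profiles, ligand_profiles)
    rows = []
    for pair in pairs:
        cells = {"pp": 0, "pa": 0, "ap": 0, "aa": 0}
        excluded = 0
        for p, lp in joined:
            ligand = lp.flag(pair.ligand_flag)
            if ligand is None:
                excluded += 1
                continue
            kir = _kir_present(p, pair)
            key = ("p" if kir else "a") + ("p" if ligand else "a")
            cells[key] += 1
        n_known = sum(cells.values())
        if excluded:
            logger.warning(
                "pair %s: %d individuals excluded (ligand status unknown)",
                pair.name,
                excluded,
            )
        row = {"pair": pair.name, "kind": pair.kind, "n": n_known,
               "n_excluded": excluded}
        for key in ("pp", "pa", "ap", "aa"):
            row[key] = cells[key]
            row[f"{key}_pct"] = (
                cells[key] / n_known * 100.0 if n_known else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def inhibitory_pair_multiplicity(profiles, ligand_profiles) -> pd.DataFrame:
    """Distribution of the number of inhibitory KIR-ligand pairs carried.

    Each individual is assigned the exact subset of the four canonical
    inhibitory pairs it satisfies (unknown ligand status counts as not
    satisfied); output rows give (cardinality, combination, n, percent)
    plus per-cardinality totals under combination="(total)".
    """
    joined = _join(profiles, ligand_profiles)
    n_total = len(joined)
    combos: dict[tuple[str, ...], int] = {}
    for p, lp in joined:
        satisfied = tuple(
            pair.name
            for pair in INHIBITORY_PAIRS
            if _kir_present(p, pair) and lp.flag(pair.ligand_flag) is True
        )
        combos[satisfied] = combos.get(satisfied, 0) + 1
    rows = []
    for card in range(len(INHIBITORY_PAIRS) + 1):
        in_card = {c: n for c, n in combos.items() if len(c) == card}
        if not in_card:
            continue
        for combo in sorted(in_card):
            rows.append(
                {
                    "cardinality": card,
                    "combination": ", ".join(combo) if combo else "(none)",
                    "n": in_card[combo],
                    "percent": in_card[combo] / n_total * 100.0,
                }
            )
        subtotal = sum(in_card.values())
        rows.append(
            {
                "cardinality": card,
                "combination": "(total)",
                "n": subtotal,
                "percent": subtotal / n_total * 100.0,
            }
        )
    return pd.DataFrame(rows)


def ligand_carriage_summary(ligand_profiles) -> pd.DataFrame:
    """Percent of individuals carrying each ligand group.

    Percentages are over individuals with known status for the flag.
    """
    if not ligand_profiles:
        raise ValueError("need at least one ligand profile")
    flags = ("C1", "C2", "Bw4", "Bw4-80I", "A3", "A11", "A3/A11", "C16")
    rows = []
    for name in flags:
        values = [lp.flag(name) for lp in ligand_profiles]
        known = [v for v in values if v is not None]
        carriers = sum(1 for v in known if v)
        rows.append(
            {
                "ligand": name,
                "n_known": len(known),
                "carriers": carriers,
                "percent": carriers / len(known) * 100.0 if known else 0.0,
            }
        )
    return pd.DataFrame(rows)
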