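"""Gene-content haplotype inference under Hardy-Weinberg equilibrium.

Presence/absence typing observes, per individual, the union of the gene
contents of two haplotypes.  Given a set of named reference haplotypes
(cen~tel motif patterns in the Vierra-Green nomenclature), the model

* enumerates, for each individual, every unordered reference pair whose
  gene-content union equals the observed content;
* maximises the multinomial HWE likelihood over haplotype frequencies
  with an EM algorithm, treating the compatible pair of each individual
  as the latent variable;
* for individuals no pair can explain, salvages a single chromosome when
  some reference's gene set is contained in the profile (the partner
  haplotype stays unexplained), so that explained/unexplained mass is
  accounted per chromosome.

Reference haplotypes must satisfy four structural rules:
(I) the framework genes are always present; (II) 2DL5 is accompanied by
2DS3 and/or 2DS5; (III) 2DL2 and 2DL3 are mutually exclusive on one
haplotype; (IV) 2DS4 implies 3DL1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .panel import DEFAULT_PANEL, GenePanel, normalize_gene_name

#: Haplotypes estimated below this chromosome count are flagged as below
#: the usual reporting threshold for gene-content inference.
MIN_CONFIDENT_COUNT = 8


@dataclass(frozen=True)
class ReferenceHaplotype:
    """A named cen~tel gene-content pattern."""

    name: str
    cen_motif: str
    tel_motif: str
    genes: frozenset[str]

    def validate(self, panel: GenePanel = DEFAULT_PANEL) -> None:
        unknown = self.genes - set(panel.genes)
        if unknown:
            raise ValueError(f"{self.name}: genes not in panel: {sorted(unknown)}")
        if not panel.framework <= self.genes:
            raise ValueError(
                f"{self.name} violates rule I: framework genes "
                f"{sorted(panel.framework - self.genes)} missing"
            )
        if "2DL5" in self.genes and not ({"2DS3", "2DS5"} & self.genes):
            raise ValueError(
                f"{self.name} violates rule II: 2DL5 present without 2DS3/2DS5"
            )
        if {"2DL2", "2DL3"} <= self.genes:
            raise ValueError(
                f"{self.name} violates rule III: 2DL2 and 2DL3 co-occur"
            )
        if "2DS4" in self.genes and "3DL1" not in self.genes:
            raise ValueError(
                f"{self.name} violates rule IV: 2DS4 present without 3DL1"
            )


def load_reference_haplotypes(
    path, panel: GenePanel = DEFAULT_PANEL
) -> list[ReferenceHaplotype]:
    """Read a reference-haplotype CSV (name, cen_motif, tel_motif, 0/1
    per gene) and validate every entry against rules I-IV."""
    df = pd.read_csv(path, dtype=str)
    for col in ("name", "cen_motif", "tel_motif"):
        if col not in df.columns:
            raise ValueError(f"reference file {path} lacks column {col!r}")
    colmap = {
        normalize_gene_name(c): c
        for c in df.columns
        if normalize_gene_name(c) in panel.genes
    }
    refs = []
    for _, row in df.iterrows():
        genes = frozenset(
            g for g, col in colmap.items() if str(row[col]).strip() == "1"
        )
        hap = ReferenceHaplotype(
            str(row["name"]).strip(),
            str(row["cen_motif"]).strip(),
            str(row["tel_motif"]).strip(),
            genes,
        )
        hap.validate(panel)
        refs.append(hap)
    names = [h.name for h in refs]
    if len(names) != len(set(names)):
        raise ValueError(f"duplicate haplotype names in {path}")
    return refs


def default_reference_haplotypes(
    panel: GenePanel = DEFAULT_PANEL,
) -> list[ReferenceHaplotype]:
    """The seven most frequent cen~tel reference haplotypes shipped with
    the package (extensible toward a full reference set via
    :func:`load_reference_haplotypes`)."""
    src = resources.files("kirpop").joinpath("data/reference_haplotypes.csv")
    with resources.as_file(src) as path:
        return load_reference_haplotypes(path, panel)


def enumerate_compatible_diplotypes(profile, refs) -> list[tuple[str, str]]:
    """All unordered reference pairs whose gene union equals the profile.

    Pairs are returned name-sorted within and across pairs; an empty list
    means no pair of references explains the genotype.
    """
    present = profile.present_set
    by_name = sorted(refs, key=lambda h: h.name)
    pairs = []
    for h1, h2 in itertools.combinations_with_replacement(by_name, 2):
        if h1.genes | h2.genes == present:
            pairs.append((h1.name, h2.name))
    return pairs


@dataclass(frozen=True)
class ResolutionSummary:
    """Per-individual resolution bookkeeping.

    ``explained_percent`` counts assigned chromosomes (two per fully
    resolved individual, one per half-resolved individual) over 2N.
    """

    n_both_resolved: int
    n_one_resolved: int
    n_unresolved: int
    explained_percent: float


def resolution_summary(
    profiles, refs, enumeration: dict[frozenset[str], list] | None = None
) -> ResolutionSummary:
    """Classify individuals as fully, half or not resolved."""
    if enumeration is None:
        enumeration = _enumerate_by_content(profiles, refs)
    singles = {h.name: h.genes for h in refs}
    n_both = n_one = n_none = 0
    for p in profiles:
        content = p.present_set
        if enumeration.get(content):
            n_both += 1
        elif any(genes <= content for genes in singles.values()):
            n_one += 1
        else:
            n_none += 1
    total_chrom = 2 * len(profiles)
    explained = (2 * n_both + n_one) / total_chrom * 100.0 if profiles else 0.0
    return ResolutionSummary(n_both, n_one, n_none, explained)


def _enumerate_by_content(profiles, refs):
    enumeration = {}
    for p in profiles:
        content = p.present_set
        if content not in enumeration:
            enumeration[content] = enumerate_compatible_diplotypes(p, refs)
    return enumeration


class HaplotypeFrequencyModel:
    """HWE multinomial model for haplotype frequencies from gene content.

    Parameters
    ----------
    profiles : sequence of GenotypeProfile
        The typed cohort.
    references : sequence of ReferenceHaplotype, optional
        Candidate haplotypes; defaults to the shipped seven-haplotype set.

    ``fit`` runs EM and returns a :class:`HaplotypeFrequencyResults`.
    """

    def __init__(self, profiles, references=None, panel: GenePanel = DEFAULT_PANEL):
        if not profiles:
            raise ValueError("need at least one profile")
        self.panel = panel
        self.profiles = list(profiles)
        self.references = (
            list(references)
            if references is not None
            else default_reference_haplotypes(panel)
        )
        if not self.references:
            raise ValueError("need at least one reference haplotype")
        self.names = [h.name for h in sorted(self.references, key=lambda h: h.name)]
        self._index = {n: i for i, n in enumerate(self.names)}
        self._genes = {h.name: h.genes for h in self.references}
        self._build_observations()

    def _build_observations(self) -> None:
        enumeration = _enumerate_by_content(self.profiles, self.references)
        pair_counts: dict[tuple[tuple[str, str], ...], int] = {}
        single_counts: dict[tuple[str, ...], int] = {}
        n_both = n_one = n_none = 0
        for p in self.profiles:
            content = p.present_set
            pairs = enumeration[content]
            if pairs:
                n_both += 1
                key = tuple(pairs)
                pair_counts[key] = pair_counts.get(key, 0) + 1
            else:
                cands = tuple(
                    sorted(n for n, g in self._genes.items() if g <= content)
                )
                if cands:
                    n_one += 1
                    single_counts[cands] = single_counts.get(cands, 0) + 1
                else:
                    n_none += 1
        self._pair_obs = [
            (
                [(self._index[a], self._index[b]) for a, b in pairs],
                count,
            )
            for pairs, count in pair_counts.items()
        ]
        self._single_obs = [
            ([self._index[n] for n in cands], count)
            for cands, count in single_counts.items()
        ]
        self.n_both, self.n_one, self.n_unresolved = n_both, n_one, n_none
        self.n_chromosomes = 2 * len(self.profiles)
        self.n_assigned = 2 * n_both + n_one
        self.resolution = ResolutionSummary(
            n_both,
            n_one,
            n_none,
            self.n_assigned / self.n_chromosomes * 100.0,
        )

    def _loglik(self, g: np.ndarray) -> float:
        ll = 0.0
        for pairs, count in self._pair_obs:
            lik = sum(
                (1.0 if i == j else 2.0) * g[i] * g[j] for i, j in pairs
            )
            ll += count * np.log(lik)
        for cands, count in self._single_obs:
            ll += count * np.log(sum(g[i] for i in cands))
        return ll

    def fit(
        self, tol: float = 1e-8, max_iter: int = 1000
    ) -> "HaplotypeFrequencyResults":
        """EM on the simplex over references; deterministic (uniform
        initialisation), converged when max |Delta f| < tol."""
        if self.n_assigned == 0:
            raise ValueError(
                "no individual is compatible with any reference haplotype"
            )
        k = len(self.names)
        g = np.full(k, 1.0 / k)
        trace = [self._loglik(g)]
        converged = False
        for _ in range(max_iter):
            counts = np.zeros(k)
            for pairs, count in self._pair_obs:
                weights = np.array(
                    [(1.0 if i == j else 2.0) * g[i] * g[j] for i, j in pairs]
                )
                weights /= weights.sum()
                for (i, j), w in zip(pairs, weights):
                    counts[i] += count * w
                    counts[j] += count * w
            for cands, count in self._single_obs:
                weights = np.array([g[i] for i in cands])
                weights /= weights.sum()
                for i, w in zip(cands, weights):
                    counts[i] += count * w
            new_g = counts / self.n_assigned
            delta = np.max(np.abs(new_g - g))
            g = new_g
            trace.append(self._loglik(g))
            if delta < tol:
                converged = True
                break
        scale = self.n_assigned / self.n_chromosomes
        freqs = {n: float(g[i] * scale) for n, i in self._index.items()}
        return HaplotypeFrequencyResults(
            model=self,
            freqs=freqs,
            cond_freqs={n: float(g[i]) for n, i in self._index.items()},
            residual=1.0 - scale,
            log_likelihood=trace,
            converged=converged,
            n_iter=len(trace) - 1,
        )


@dataclass
class HaplotypeFrequencyResults:
    """EM haplotype-frequency estimates.

    ``freqs`` are fractions of all 2N chromosomes (they sum to
    1 - ``residual``); ``cond_freqs`` renormalise over the assigned
    chromosomes and lie on the simplex.
    """

    model: HaplotypeFrequencyModel
    freqs: dict[str, float]
    cond_freqs: dict[str, float]
    residual: float
    log_likelihood: list[float]
    converged: bool
    n_iter: int

    @property
    def n_chromosomes(self) -> int:
        return self.model.n_chromosomes

    @property
    def resolution(self) -> ResolutionSummary:
        return self.model.resolution

    def frequency_table(self) -> pd.DataFrame:
        """Name, nomenclature, chromosome count and percent, sorted by
        descending count then name; zero-frequency haplotypes omitted.

        Rows with fewer than eight estimated chromosomes are flagged as
        below the usual confidence threshold for gene-content inference.
        """
        rows = []
        for name, f in self.freqs.items():
            if f <= 0.0:
                continue
            count = round(f * self.n_chromosomes)
            rows.append(
                {
                    "haplotype": name,
                    "count": count,
                    "percent": f * 100.0,
                    "below_confidence_threshold": count < MIN_CONFIDENT_COUNT,
                }
            )
        rows.sort(key=lambda r: (-r["count"], r["haplotype"]))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        res = self.resolution
        lines = [
            "HWE haplotype frequency estimates (EM)",
            f"  individuals: {len(self.model.profiles)}"
            f"  chromosomes: {self.n_chromosomes}",
            f"  iterations: {self.n_iter}  converged: {self.converged}",
            f"  log-likelihood: {self.log_likelihood[-1]:.4f}",
            f"  resolved both/one/none: {res.n_both_resolved}/"
            f"{res.n_one_resolved}/{res.n_unresolved}",
            f"  explained chromosome mass: {res.explained_percent:.2f}%"
            f"  residual: {self.residual * 100.0:.2f}%",
            "",
            f"  {'haplotype':<22}{'count':>7}{'percent':>10}",
        ]
        table = self.frequency_table()
        for _, row in table.iterrows():
            flag = " *" if row["below_confidence_threshold"] else ""
            lines.append(
                f"  {row['haplotype']:<22}{row['count']:>7}"
                f"{row['percent']:>10.3f}{flag}"
            )
        if table["below_confidence_threshold"].any():
            lines.append("  * fewer than 8 chromosomes; interpret with caution")
        return "\n".join(lines)


def frequency_table_from_counts(
    counts: dict[str, int], n_chromosomes: int
) -> pd.DataFrame:
    """Table of (haplotype, count, percent) from fixed chromosome counts.

    Percent = count / 2N x 100; ordering and confidence flagging match
    :meth:`HaplotypeFrequencyResults.frequency_table`.
    """
    if n_chromosomes <= 0:
        raise ValueError("n_chromosomes must be positive")
    rows = [
        {
            "haplotype": name,
            "count": count,
            "percent": count / n_chromosomes * 100.0,
            "below_confidence_threshold": count < MIN_CONFIDENT_COUNT,
        }
        for name, count in counts.items()
        if count > 0
    ]
    rows.sort(key=lambda r: (-r["count"], r["haplotype"]))
    return pd.DataFrame(rows)


def em_haplotype_frequencies(
    profiles, refs=None, tol: float = 1e-8, max_iter: int = 1000
) -> HaplotypeFrequencyResults:
    """Functional wrapper: build the model and fit in one call."""
    return HaplotypeFrequencyModel(profiles, refs).fit(tol=tol, max_iter=max_iter)


def haplotype_frequency_table(results: HaplotypeFrequencyResults) -> pd.DataFrame:
    return results.frequency_table()
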