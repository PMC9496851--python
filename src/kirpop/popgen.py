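"""Inter-population comparison on KIR carrier-frequency tables.

Populations are compared on per-locus carrier frequencies, each locus
treated as biallelic (presence p, absence 1-p).  The toolbox covers
Nei's (1972) standard genetic distance, neighbor-joining dendrograms
with Newick output, principal component analysis of the frequency
matrix, and agglomerative clustering for heatmap rendering.

Carrier frequencies (not Bernstein gene frequencies) are the default
input scale; ``use_gene_frequencies`` converts a table for sensitivity
analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .frequency_stats import bernstein_gene_frequency

logger = logging.getLogger(__name__)


class PopulationFrequencyTable:
    """Population x gene frequency matrix in [0, 1].

    ``from_csv`` expects rows = populations with a ``population`` column
    (optional ``n`` and ``region`` columns) and one column per gene.
    AFND-style percent tables are auto-detected (any value > 1) and
    divided by 100 with a log message.
    """

    def __init__(self, values: pd.DataFrame, sample_sizes=None):
        if values.isna().any().any():
            raise ValueError("frequency table contains missing cells")
        arr = values.to_numpy(dtype=float)
        if (arr < 0).any() or (arr > 1).any():
            raise ValueError("frequencies must lie in [0, 1]")
        self.values = values.astype(float)
        self.sample_sizes = sample_sizes

    @property
    def populations(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_csv(cls, path) -> "PopulationFrequencyTable":
        df = pd.read_csv(path)
        if "population" not in df.columns:
            raise ValueError(f"{path} lacks a 'population' column")
        df = df.set_index("population")
        sizes = df.pop("n") if "n" in df.columns else None
        if "region" in df.columns:
            df = df.drop(columns="region")
        if (df.to_numpy(dtype=float) > 1).any():
            logger.info("values > 1 detected in %s; interpreting as percent", path)
            df = df / 100.0
        return cls(df, sizes)

    def restrict_genes(self, genes) -> "PopulationFrequencyTable":
        """Restrict the analysis to a common gene set (e.g. the 14-locus
        panel when pseudogene frequencies are unavailable); never imputes."""
        missing = set(genes) - set(self.genes)
        if missing:
            raise ValueError(f"genes absent from table: {sorted(missing)}")
        return PopulationFrequencyTable(self.values[list(genes)], self.sample_sizes)

    def as_gene_frequencies(self) -> "PopulationFrequencyTable":
        return PopulationFrequencyTable(
            self.values.map(bernstein_gene_frequency), self.sample_sizes
        )


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        finite = np.isfinite(m)
        if not np.allclose(m[finite], m.T[finite]):
            raise ValueError("distance matrix must be symmetric")
        if (m[finite] < 0).any():
            raise ValueError("distances must be nonnegative")
        self.matrix = m

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def to_phylip(self) -> str:
        """Lower-triangular PHYLIP distance format."""
        lines = [f"    {len(self.labels)}"]
        for i, label in enumerate(self.labels):
            row = " ".join(f"{self.matrix[i, j]:.6f}" for j in range(i))
            lines.append(f"{label[:10]:<10}  {row}".rstrip())
        return "\n".join(lines) + "\n"


def nei_distance(table: PopulationFrequencyTable) -> DistanceMatrix:
    """Nei's (1972) standard genetic distance over biallelic loci.

    For populations x and y with per-locus presence frequencies p, q:
    J_x = sum_l (p_l^2 + (1-p_l)^2), likewise J_y and
    J_xy = sum_l (p_l q_l + (1-p_l)(1-q_l)); D = -ln(J_xy/sqrt(J_x J_y)).
    Identical populations have D = 0 even at fixed loci; a zero identity
    yields +inf, reported explicitly.
    """
    p = table.values.to_numpy(dtype=float)
    n = p.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            x, y = p[i], p[j]
            jx = float(np.sum(x**2 + (1 - x) ** 2))
            jy = float(np.sum(y**2 + (1 - y) ** 2))
            jxy = float(np.sum(x * y + (1 - x) * (1 - y)))
            if jxy == 0.0:
                d = math.inf
            else:
                d = max(0.0, -math.log(jxy / math.sqrt(jx * jy)))
            out[i, j] = out[j, i] = d
    return DistanceMatrix(table.populations, out)


def neighbor_joining(dist: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns a Newick string.

    Ties in the Q criterion break on the lowest label-index pair, so the
    output is deterministic.  Negative branch lengths are clamped to
    zero with the deficit moved to the adjacent (sister) branch, a
    common convention the additive case never triggers.
    """
    n = len(dist.labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    if not np.isfinite(dist.matrix).all():
        raise ValueError("neighbor joining requires finite distances")
    if n == 2:
        d = dist.matrix[0, 1]
        return (
            f"({_quote(dist.labels[0])}:{d / 2:.10g},"
            f"{_quote(dist.labels[1])}:{d / 2:.10g});"
        )

    d = dist.matrix.astype(float).copy()
    nodes = [_quote(label) for label in dist.labels]
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        sums = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for bj in range(ai + 1, m):
                i, j = active[ai], active[bj]
                q = (m - 2) * d[i, j] - sums[i] - sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        limb_i = 0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        limb_j = d[i, j] - limb_i
        if limb_i < 0:
            limb_j += -limb_i  # move the deficit to the sister branch
            limb_i = 0.0
        elif limb_j < 0:
            limb_i += -limb_j
            limb_j = 0.0
        new = f"({nodes[i]}:{limb_i:.10g},{nodes[j]}:{limb_j:.10g})"
        # distances from the new internal node
        row = np.zeros(d.shape[0] + 1)
        grown = np.zeros((d.shape[0] + 1, d.shape[0] + 1))
        grown[: d.shape[0], : d.shape[0]] = d
        for k in active:
            if k in (i, j):
                continue
            row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        grown[-1, :-1] = row[:-1]
        grown[:-1, -1] = row[:-1]
        d = grown
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    i, j = active
    return f"({nodes[i]},{nodes[j]}:{d[i, j]:.10g});"


def _quote(label: str) -> str:
    if any(c in label for c in " (),:;'"):
        return "'" + label.replace("'", "''") + "'"
    return label


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray


def pca_frequencies(
    table: PopulationFrequencyTable, standardize: bool = True
) -> PCAResult:
    """PCA of the population x gene frequency matrix via SVD.

    Columns are centred and, with ``standardize`` (the default,
    producing a correlation biplot), scaled to unit variance; zero-
    variance genes are dropped with a warning in that case.  The sign of
    each component is fixed so its largest-magnitude loading is
    positive.
    """
    x = table.values.copy()
    if x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least two populations and two genes")
    if standardize:
        sd = x.std(axis=0, ddof=1)
        dropped = list(sd.index[sd == 0.0])
        if dropped:
            logger.warning("dropping zero-variance genes: %s", dropped)
            x = x.drop(columns=dropped)
            sd = sd.drop(dropped)
        x = (x - x.mean(axis=0)) / sd
    else:
        x = x - x.mean(axis=0)

    arr = x.to_numpy(dtype=float)
    u, s, vt = np.linalg.svd(arr, full_matrices=False)
    # fix signs: largest-|loading| positive per component
    for k in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    var = s**2
    ratio = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    comps = [f"PC{k + 1}" for k in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=x.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=x.columns, columns=comps),
        explained_variance_ratio=ratio,
    )


@dataclass
class ClusteringResult:
    linkage: np.ndarray
    leaf_order: list[str]
    labels: list[str]

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def hierarchical_clustering(
    table: PopulationFrequencyTable,
    metric: str = "euclidean",
    method: str = "complete",
) -> ClusteringResult:
    """Agglomerative clustering over population rows for heatmaps."""
    arr = table.values.to_numpy(dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least two populations")
    z = hierarchy.linkage(pdist(arr, metric=metric), method=method)
    order = hierarchy.leaves_list(z)
    labels = table.populations
    return ClusteringResult(z, [labels[i] for i in order], labels)
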