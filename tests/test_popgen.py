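"""Nei distance, neighbor joining, PCA and hierarchical clustering."""

import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from kirpop import (
    DistanceMatrix,
    PopulationFrequencyTable,
    hierarchical_clustering,
    neighbor_joining,
    nei_distance,
    pca_frequencies,
)


def table_from_array(arr, pops=None, genes=None):
    arr = np.asarray(arr, dtype=float)
    pops = pops or [f"pop{i}" for i in range(arr.shape[0])]
    genes = genes or [f"g{j}" for j in range(arr.shape[1])]
    return PopulationFrequencyTable(pd.DataFrame(arr, index=pops, columns=genes))


def nei_oracle(x, y):
    """Independent per-locus summation of Nei's standard distance."""
    jx = jy = jxy = 0.0
    for p, q in zip(x, y):
        jx += p * p + (1 - p) * (1 - p)
        jy += q * q + (1 - q) * (1 - q)
        jxy += p * q + (1 - p) * (1 - q)
    return -math.log(jxy / math.sqrt(jx * jy))


def random_additive_tree(rng, n_taxa):
    """A random binary tree topology with positive branch lengths and
    its implied leaf-to-leaf path-length matrix."""
    # build by sequential attachment: edges as dict node -> (parent, length)
    next_node = n_taxa
    edges = {}
    nodes = [0, 1]
    edges[0] = (None, 0.0)
    # represent as adjacency with lengths
    adj = {0: {}, 1: {}}
    length = lambda: rng.uniform(0.05, 1.0)
    w = length()
    adj[0][1] = w
    adj[1][0] = w
    for leaf in range(2, n_taxa):
        # pick a random existing edge, split it with a new internal node
        a = rng.choice([u for u in adj for _ in adj[u]])
        b = rng.choice(list(adj[a]))
        w = adj[a][b]
        mid, adj[a][b] = next_node, None
        next_node += 1
        del adj[a][b]
        del adj[b][a]
        t = rng.uniform(0.2, 0.8) * w
        adj[mid] = {a: t, b: w - t}
        adj[a][mid] = t
        adj[b][mid] = w - t
        wl = length()
        adj[leaf] = {mid: wl}
        adj[mid][leaf] = wl
    # all-pairs path lengths among leaves by BFS
    def dist_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    m = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        d = dist_from(i)
        for j in range(n_taxa):
            m[i, j] = d[j]
    np.fill_diagonal(m, 0.0)
    return m


def patristic_matrix(newick, labels):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                out[i, j] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return out


class TestNeiDistance:
    def test_self_distance_zero_and_symmetry(self):
        rng = np.random.default_rng(0)
        table = table_from_array(rng.uniform(0.05, 0.95, size=(5, 16)))
        dist = nei_distance(table)
        assert np.allclose(np.diag(dist.matrix), 0.0)
        assert np.allclose(dist.matrix, dist.matrix.T)

    def test_matches_independent_oracle(self):
        rng = np.random.default_rng(42)
        arr = rng.uniform(0.0, 1.0, size=(6, 10))
        dist = nei_distance(table_from_array(arr))
        for i in range(6):
            for j in range(i + 1, 6):
                assert dist.matrix[i, j] == pytest.approx(
                    nei_oracle(arr[i], arr[j]), abs=1e-12
                )

    def test_hand_computed_single_locus(self):
        dist = nei_distance(table_from_array([[0.8], [0.6]]))
        expected = -math.log(
            (0.8 * 0.6 + 0.2 * 0.4) / math.sqrt((0.64 + 0.04) * (0.36 + 0.16))
        )
        assert dist.matrix[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_boundary_identity_and_infinity(self):
        dist = nei_distance(table_from_array([[0.5], [0.5]]))
        assert dist.matrix[0, 1] == 0.0
        dist = nei_distance(table_from_array([[1.0], [0.0]]))
        assert math.isinf(dist.matrix[0, 1])

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(7)
        arr = rng.uniform(0.1, 0.9, size=(4, 8))
        d1 = nei_distance(table_from_array(arr))
        perm = rng.permutation(8)
        d2 = nei_distance(table_from_array(arr[:, perm]))
        assert np.allclose(d1.matrix, d2.matrix)

    def test_identical_fixed_populations(self):
        dist = nei_distance(table_from_array([[1.0, 0.0], [1.0, 0.0]]))
        assert dist.matrix[0, 1] == 0.0

    def test_phylip_output_shape(self):
        dist = nei_distance(table_from_array([[0.4, 0.5], [0.2, 0.9], [0.6, 0.1]]))
        text = dist.to_phylip()
        assert text.splitlines()[0].strip() == "3"


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        labels = ["A", "B", "C"]
        newick = neighbor_joining(DistanceMatrix(labels, d))
        m = patristic_matrix(newick, labels)
        # a = (d_AB + d_AC - d_BC)/2 = 1, b = 2, c = 3
        assert np.allclose(m, d, atol=1e-9)

    def test_two_taxa(self):
        newick = neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0, 2.0], [2.0, 0]])))
        m = patristic_matrix(newick, ["A", "B"])
        assert m[0, 1] == pytest.approx(2.0)

    def test_recovers_random_additive_matrices(self):
        rng = np.random.default_rng(123)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            m = random_additive_tree(rng, n)
            labels = [f"T{i}" for i in range(n)]
            newick = neighbor_joining(DistanceMatrix(labels, m))
            rec = patristic_matrix(newick, labels)
            assert np.allclose(rec, m, atol=1e-9)

    def test_newick_reparses_to_same_tree(self):
        rng = np.random.default_rng(5)
        m = random_additive_tree(rng, 6)
        labels = [f"T{i}" for i in range(6)]
        newick = neighbor_joining(DistanceMatrix(labels, m))
        tree = dendropy.Tree.get(data=newick, schema="newick")
        assert {t.label for t in tree.taxon_namespace} == set(labels)

    def test_equidistant_matrix_deterministic(self):
        m = np.ones((4, 4)) - np.eye(4)
        labels = list("ABCD")
        first = neighbor_joining(DistanceMatrix(labels, m))
        assert first == neighbor_joining(DistanceMatrix(labels, m))

    def test_rejects_infinite_distances(self):
        m = np.array([[0.0, math.inf], [math.inf, 0.0]])
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], m))


class TestDistanceMatrixValidation:
    def test_asymmetric_rejected(self):
        m = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["A", "B"], m)

    def test_negative_rejected(self):
        m = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError, match="nonnegative"):
            DistanceMatrix(["A", "B"], m)


class TestPCA:
    def test_identical_populations_score_at_origin(self):
        table = table_from_array([[0.5, 0.2, 0.7], [0.5, 0.2, 0.7]])
        res = pca_frequencies(table, standardize=False)
        assert np.allclose(res.scores.to_numpy(), 0.0)

    def test_reconstruction_of_centered_matrix(self):
        rng = np.random.default_rng(21)
        arr = rng.uniform(0, 1, size=(6, 10))
        table = table_from_array(arr)
        res = pca_frequencies(table, standardize=False)
        rec = res.scores.to_numpy() @ res.loadings.to_numpy().T
        assert np.allclose(rec, arr - arr.mean(axis=0), atol=1e-10)

    def test_single_informative_gene_dominates_pc1(self):
        arr = np.full((3, 5), 0.5)
        arr[:, 2] = [0.1, 0.5, 0.9]
        res = pca_frequencies(table_from_array(arr), standardize=False)
        loadings = res.loadings["PC1"].abs()
        assert loadings.idxmax() == "g2"
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_variance_ratios_sorted_and_sum_to_one(self):
        rng = np.random.default_rng(2)
        res = pca_frequencies(table_from_array(rng.uniform(0, 1, (7, 12))))
        r = res.explained_variance_ratio
        assert np.all(np.diff(r) <= 1e-12)
        assert r.sum() == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(4)
        res = pca_frequencies(table_from_array(rng.uniform(0, 1, (8, 6))))
        v = res.loadings.to_numpy()
        assert np.allclose(v.T @ v, np.eye(v.shape[1]), atol=1e-10)

    def test_zero_variance_gene_dropped_when_standardizing(self):
        arr = np.column_stack([np.full(4, 0.5), np.linspace(0.1, 0.9, 4)])
        res = pca_frequencies(table_from_array(arr, genes=["flat", "varies"]))
        assert list(res.loadings.index) == ["varies"]

    def test_sign_convention(self):
        rng = np.random.default_rng(8)
        res = pca_frequencies(table_from_array(rng.uniform(0, 1, (5, 5))))
        for col in res.loadings.columns:
            v = res.loadings[col]
            assert v[v.abs().idxmax()] > 0


class TestHierarchicalClustering:
    def test_two_populations_merge_at_euclidean_distance(self):
        arr = np.array([[0.0, 0.0], [0.3, 0.4]])
        res = hierarchical_clustering(table_from_array(arr))
        assert res.merge_heights()[0] == pytest.approx(0.5)

    def test_outlier_merges_last(self):
        arr = np.array([[0.1, 0.1], [0.12, 0.1], [0.9, 0.9]])
        res = hierarchical_clustering(table_from_array(arr, pops=["a", "b", "out"]))
        # the last merge joins the outlier's singleton cluster
        assert res.leaf_order[0] == "out" or res.leaf_order[-1] == "out"
        heights = res.merge_heights()
        assert heights[-1] > heights[0]

    def test_identical_rows_merge_at_zero(self):
        arr = np.array([[0.5, 0.5], [0.5, 0.5], [0.9, 0.1]])
        res = hierarchical_clustering(table_from_array(arr))
        assert res.merge_heights()[0] == pytest.approx(0.0)


class TestFrequencyTableIO:
    def test_percent_autodetect(self, tmp_path):
        path = tmp_path / "freqs.csv"
        path.write_text(
            "population,n,2DL1,2DL2\nMedellin,161,95,54\nOther,100,80,40\n"
        )
        table = PopulationFrequencyTable.from_csv(path)
        assert table.values.loc["Medellin", "2DL1"] == pytest.approx(0.95)

    def test_missing_cells_rejected(self):
        df = pd.DataFrame({"a": [0.1, np.nan]}, index=["x", "y"])
        with pytest.raises(ValueError, match="missing"):
            PopulationFrequencyTable(df)

    def test_restrict_genes(self):
        table = table_from_array(
            np.full((2, 3), 0.5), genes=["2DL1", "2DP1", "3DP1"]
        )
        sub = table.restrict_genes(["2DL1"])
        assert sub.genes == ["2DL1"]
        with pytest.raises(ValueError, match="absent"):
            table.restrict_genes(["3DS1"])

    def test_gene_frequency_conversion(self):
        table = table_from_array(np.array([[0.75]]), pops=["p"], genes=["g"])
        conv = table.as_gene_frequencies()
        assert conv.values.iloc[0, 0] == pytest.approx(0.5)
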