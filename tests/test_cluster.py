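"""Normalization, PCA, batch centering, Louvain clustering, lineage."""

import igraph as ig
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from myotcell import cluster as cl
from myotcell.containers import NormalizedMatrix
from conftest import toy_matrix
import oracles

TWO_TRIANGLES = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]


def _nm(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    meta = pd.DataFrame({"patient": "P1", "compartment": "muscle",
                         "timepoint": "T1", "batch": "B1",
                         "treatment": "early"},
                        index=pd.Index(cells, name="cell_id"))
    return NormalizedMatrix(values=values, gene_ids=np.array(genes, object),
                            cell_ids=np.array(cells, object), cell_meta=meta)


class TestNormalize:
    def test_direct_formula(self):
        m = toy_matrix([[1.0], [3.0], [6.0]], ["g1", "g2", "g3"])
        nm = cl.normalize_cp10k_log(m)
        assert nm.values[0, 0] == pytest.approx(np.log(1 + 1000), abs=1e-9)

    def test_symmetry_equal_genes(self):
        m = toy_matrix([[5.0], [5.0]], ["g1", "g2"])
        nm = cl.normalize_cp10k_log(m)
        assert nm.values[0, 0] == nm.values[1, 0] == pytest.approx(np.log(5001))

    def test_cp10k_invariant_on_cohort(self, clean_cohort):
        clean, _ = clean_cohort
        nm = cl.normalize_cp10k_log(clean)
        totals = np.expm1(nm.values).sum(axis=0)
        np.testing.assert_allclose(totals, 1e4, rtol=1e-6)

    def test_zero_total_cell_names_cell(self):
        m = toy_matrix([[0.0, 1.0], [0.0, 2.0]], ["g1", "g2"])
        with pytest.raises(ValueError, match="c1"):
            cl.normalize_cp10k_log(m)


class TestPCA:
    def test_matches_dense_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        nm = _nm(rng.normal(2, 1, size=(5, 6)))
        emb = cl.pca_embed(nm, k=3, scale=False)
        X = nm.values.T
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (X.shape[0] - 1))
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for i in range(3):
            v = evecs[:, i]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(emb.coordinates[:, i], Xc @ v,
                                       atol=1e-8)
            assert emb.explained_variance[i] == pytest.approx(evals[i],
                                                              abs=1e-8)

    def test_degenerate_variance_confined_to_pc1(self):
        values = np.array([[1.0, 2.0, 3.0, 4.0], [7.0, 7.0, 7.0, 7.0]])
        emb = cl.pca_embed(_nm(values), k=2, scale=False)
        assert emb.explained_variance[1] == 0.0
        # PC1 is the centered gene-1 axis itself
        np.testing.assert_allclose(emb.coordinates[:, 0],
                                   values[0] - values[0].mean(), atol=1e-12)
        np.testing.assert_allclose(emb.coordinates[:, 1], 0.0)

    def test_total_explained_bounded_by_total_variance(self):
        rng = np.random.default_rng(2)
        nm = _nm(rng.gamma(2, 1, size=(10, 12)))
        emb = cl.pca_embed(nm, k=5, scale=False)
        total = nm.values.T.var(axis=0, ddof=1).sum()
        assert emb.explained_variance.sum() <= total + 1e-9
        assert (np.diff(emb.explained_variance) <= 1e-12).all()

    def test_k_beyond_dimensions_raises(self):
        nm = _nm(np.ones((3, 4)))
        with pytest.raises(ValueError, match="exceeds"):
            cl.pca_embed(nm, k=5)


class TestBatchAdjust:
    def _embedding(self, coords, batches):
        cells = [f"c{i}" for i in range(len(coords))]
        e = cl.PCEmbedding(coordinates=np.asarray(coords, dtype=float),
                           explained_variance=np.ones(2), center=np.zeros(2),
                           cell_ids=np.array(cells, object))
        return e, pd.Series(batches, index=cells)

    def test_single_batch_identity(self):
        e, b = self._embedding([[0, 1], [2, 3], [4, 5]], ["A", "A", "A"])
        out = cl.adjust_batch(e, b)
        np.testing.assert_array_equal(out.coordinates, e.coordinates)

    def test_two_batches_centered(self):
        rng = np.random.default_rng(3)
        base = rng.normal(0, 1, size=(40, 2))
        coords = base.copy()
        coords[20:, 0] += 5.0  # batch offset on PC1
        e, b = self._embedding(coords, ["A"] * 20 + ["B"] * 20)
        out = cl.adjust_batch(e, b)
        mean_a = out.coordinates[:20].mean(axis=0)
        mean_b = out.coordinates[20:].mean(axis=0)
        np.testing.assert_allclose(mean_a, mean_b, atol=1e-9)
        # within-batch pairwise geometry untouched
        from scipy.spatial.distance import pdist
        np.testing.assert_allclose(pdist(out.coordinates[:20]),
                                   pdist(coords[:20]), atol=1e-9)

    def test_singleton_batch_left_with_warning(self):
        e, b = self._embedding([[0, 0], [4, 0], [8, 0]], ["A", "A", "B"])
        with pytest.warns(UserWarning, match="single cell"):
            out = cl.adjust_batch(e, b)
        np.testing.assert_array_equal(out.coordinates[2], e.coordinates[2])

    def test_reduces_between_batch_variance_on_cohort(self, clean_cohort):
        clean, _ = clean_cohort
        nm = cl.normalize_cp10k_log(clean)
        mask = (nm.cell_meta["compartment"] == "muscle").to_numpy()
        sub = nm.subset_cells(mask)
        emb = cl.pca_embed(sub, k=8)
        adj = cl.adjust_batch(emb, sub.cell_meta["batch"])

        def between_var(e):
            df = pd.DataFrame(e.coordinates)
            df["b"] = sub.cell_meta["batch"].to_numpy()
            return df.groupby("b").mean().var().sum()

        assert between_var(adj) < between_var(emb)


class TestLouvain:
    def test_two_triangles_partition_and_modularity(self):
        g = ig.Graph(n=6, edges=TWO_TRIANGLES)
        g.es["weight"] = [1.0] * len(TWO_TRIANGLES)
        labels, modularity = cl.louvain_partition(g, seed=0)
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1
        assert labels[0] != labels[3]
        assert modularity == pytest.approx(5 / 14, abs=1e-9)

    def test_two_triangles_is_bruteforce_optimum(self):
        best_q, best_p = oracles.best_modularity_partition(TWO_TRIANGLES, 6)
        assert best_q == pytest.approx(5 / 14, abs=1e-12)
        assert sorted(sorted(b) for b in best_p) == [[0, 1, 2], [3, 4, 5]]

    def test_two_blob_recovery(self):
        rng = np.random.default_rng(4)
        blob1 = rng.normal(0, 0.1, size=(30, 3))
        blob2 = rng.normal(3, 0.1, size=(30, 3))
        coords = np.vstack([blob1, blob2])
        cells = np.array([f"c{i}" for i in range(60)], object)
        e = cl.PCEmbedding(coordinates=coords, explained_variance=np.ones(3),
                           center=np.zeros(3), cell_ids=cells)
        ca = cl.knn_louvain(e, k_neighbors=20, resolution=1.0, seed=0)
        truth = [0] * 30 + [1] * 30
        assert adjusted_rand_score(truth, ca.labels.to_numpy()) == 1.0

    def test_same_seed_same_labels(self, muscle_nm):
        sub, _ = muscle_nm
        emb = cl.pca_embed(sub, k=8)
        a = cl.knn_louvain(emb, seed=7)
        b = cl.knn_louvain(emb, seed=7)
        assert a.labels.equals(b.labels)

    def test_planted_cluster_recovery_across_seeds(self, muscle_nm):
        sub, labels = muscle_nm
        emb = cl.pca_embed(sub, k=8)
        emb = cl.adjust_batch(emb, sub.cell_meta["batch"])
        for seed in range(5):
            ca = cl.knn_louvain(emb, k_neighbors=20, seed=seed)
            ari = adjusted_rand_score(labels.to_numpy(), ca.labels.to_numpy())
            assert ari >= 0.8


class TestCompositionAndLineage:
    def test_composition_fractions(self):
        labels = pd.Series([1, 1, 1, 2], index=["a", "b", "c", "d"])
        ca = cl.ClusterAssignment(labels=labels, modularity=0.0)
        meta = pd.DataFrame({"patient": ["P1"] * 4},
                            index=["a", "b", "c", "d"])
        table = cl.cluster_composition(ca, meta)
        assert table.set_index("cluster")["fraction"].to_dict() == \
            {1: 0.75, 2: 0.25}

    def test_single_cluster_fraction_one(self):
        labels = pd.Series([1, 1], index=["a", "b"])
        ca = cl.ClusterAssignment(labels=labels, modularity=0.0)
        meta = pd.DataFrame({"patient": ["P1", "P1"]}, index=["a", "b"])
        assert cl.cluster_composition(ca, meta)["fraction"].tolist() == [1.0]

    @pytest.mark.parametrize("cd4,cd8a,cd8b,expected", [
        (0.0, 2.0, 0.0, "CD8"),
        (1.5, 0.2, 0.0, "CD4"),
        (0.0, 0.0, 0.0, "DN"),
        (1.0, 1.0, 0.0, "DN"),  # tie at positive values
    ])
    def test_lineage_rule(self, cd4, cd8a, cd8b, expected):
        nm = _nm(np.array([[cd4], [cd8a], [cd8b]]), ["CD4", "CD8A", "CD8B"])
        assert cl.assign_lineage(nm).iloc[0] == expected

    def test_lineage_missing_genes_raises(self):
        nm = _nm(np.ones((2, 2)), ["CD4", "CD8A"])
        with pytest.raises(ValueError, match="CD8B"):
            cl.assign_lineage(nm)
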