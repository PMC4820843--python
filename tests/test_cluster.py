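"""PCA, top-loading gene selection and hierarchical clustering."""

import numpy as np
import pytest

from hscbias import (
    ExpressionMatrix,
    cluster_concordance,
    hierarchical_cluster,
    run_pca,
    top_loading_genes,
)


def _expr(values, scale="log2cpm1", groups=None):
    g = [f"g{i}" for i in range(values.shape[0])]
    c = [f"c{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(g, c, values, scale, groups or {ci: "x" for ci in c})


class TestPca:
    def test_single_varying_gene_dominates_pc1(self):
        vals = np.ones((4, 6))
        vals[0] = [0, 2, 4, 6, 8, 10]
        pca = run_pca(_expr(vals), n_components=2)
        assert pca.explained_variance[0] > 0.999
        assert abs(pca.loadings[0, 0]) > 0.999

    def test_scores_match_eigendecomposition_oracle(self):
        """Brute-force eigensolver of the cell covariance reproduces scores."""
        rng = np.random.default_rng(5)
        vals = rng.gamma(2.0, 2.0, size=(5, 4))
        pca = run_pca(_expr(vals), n_components=3)
        X = vals.T - vals.T.mean(axis=0)  # cells x genes, gene-centered
        evals, evecs = np.linalg.eigh(X @ X.T)  # Gram matrix of cells
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        for j in range(3):
            score_oracle = evecs[:, j] * np.sqrt(max(evals[j], 0))
            got = pca.scores[:, j]
            assert np.allclose(got, score_oracle, atol=1e-8) or np.allclose(
                got, -score_oracle, atol=1e-8
            )
        total = evals.sum()
        np.testing.assert_allclose(
            pca.explained_variance, evals[:3] / total, atol=1e-10
        )

    def test_duplicated_cells_get_identical_scores(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2.0, 2.0, size=(6, 3))
        doubled = np.hstack([vals, vals])
        pca = run_pca(_expr(doubled), n_components=2)
        np.testing.assert_allclose(pca.scores[:3], pca.scores[3:], atol=1e-8)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            run_pca(_expr(np.ones((3, 2))), n_components=3)

    def test_loadings_bounded(self):
        rng = np.random.default_rng(1)
        pca = run_pca(_expr(rng.gamma(1, 1, (30, 20))), n_components=5)
        assert np.all(np.abs(pca.loadings) <= 1 + 1e-12)

    def test_score_columns_orthogonal(self):
        rng = np.random.default_rng(2)
        pca = run_pca(_expr(rng.gamma(1, 1, (30, 20))), n_components=4)
        gram = pca.scores.T @ pca.scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8


class TestTopLoadingGenes:
    def test_gene_equal_to_score_ranks_first(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(5, 1, size=(20, 40)).clip(min=0)
        pca = run_pca(_expr(vals), n_components=2)
        vals2 = np.vstack([vals, (pca.scores[:, 0] - pca.scores[:, 0].min())])
        pca2 = run_pca(_expr(vals2), n_components=2)
        top = top_loading_genes(pca2, n_components=2, k=1)
        assert top == ["g20"]

    def test_invariant_under_component_sign_flip(self):
        rng = np.random.default_rng(4)
        pca = run_pca(_expr(rng.gamma(2, 2, (30, 25))), n_components=3)
        flipped = type(pca)(
            cell_ids=pca.cell_ids,
            gene_ids=pca.gene_ids,
            scores=-pca.scores,
            loadings=-pca.loadings,
            explained_variance=pca.explained_variance,
        )
        assert top_loading_genes(pca, k=10) == top_loading_genes(flipped, k=10)

    def test_pure_noise_gene_excluded(self):
        """A noise gene among structured genes has near-zero loading."""
        rng = np.random.default_rng(6)
        n = 200
        signal = np.linspace(0, 10, n)
        vals = np.vstack(
            [np.tile(signal, (10, 1)) + rng.normal(0, 0.5, (10, n)),
             rng.normal(5, 1, (1, n))]
        ).clip(min=0)
        pca = run_pca(_expr(vals), n_components=1)
        assert abs(pca.loadings[-1, 0]) < 0.3
        assert "g10" not in top_loading_genes(pca, n_components=1, k=5)

    def test_k_equal_gene_count_returns_all(self):
        rng = np.random.default_rng(7)
        pca = run_pca(_expr(rng.gamma(2, 2, (8, 10))), n_components=2)
        assert sorted(top_loading_genes(pca, n_components=2, k=8)) == sorted(pca.gene_ids)

    def test_k_too_large_rejected(self):
        rng = np.random.default_rng(8)
        pca = run_pca(_expr(rng.gamma(2, 2, (8, 10))), n_components=2)
        with pytest.raises(ValueError, match="k="):
            top_loading_genes(pca, n_components=2, k=9)


class TestHierarchicalCluster:
    def test_identical_and_anticorrelated_distances(self):
        vals = np.array(
            [[1.0, 1.0, 3.0], [2.0, 2.0, 2.0], [3.0, 3.0, 1.0]]
        )  # c0 == c1, c2 anti-correlated with them
        x = _expr(vals)
        d = hierarchical_cluster(x, x.gene_ids)
        from scipy.spatial.distance import pdist

        dist = pdist(vals.T, metric="correlation")
        assert dist[0] == pytest.approx(0.0, abs=1e-12)  # identical profiles
        assert dist[1] == pytest.approx(2.0, abs=1e-12)  # perfect anti-correlation
        assert d.cut(2)["c0"] == d.cut(2)["c1"] != d.cut(2)["c2"]

    def test_two_well_separated_groups_recovered(self):
        """All-pairs check: within-group distances below between-group ones."""
        base_a = np.array([5.0, 1.0, 4.0, 2.0, 6.0])
        base_b = np.array([1.0, 5.0, 2.0, 6.0, 1.0])
        rng = np.random.default_rng(9)
        cols = [base_a + rng.normal(0, 0.1, 5) for _ in range(3)] + [
            base_b + rng.normal(0, 0.1, 5) for _ in range(3)
        ]
        vals = np.array(cols).T
        x = _expr(vals)
        labels = hierarchical_cluster(x, x.gene_ids).cut(2)
        groups = ["A"] * 3 + ["B"] * 3
        assert cluster_concordance([labels[c] for c in x.cell_ids], groups) == 1.0

    def test_constant_cell_named_in_error(self):
        vals = np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]])
        x = _expr(vals)
        with pytest.raises(ValueError, match="c0"):
            hierarchical_cluster(x, x.gene_ids)

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(10)
        x = _expr(rng.gamma(2, 2, (10, 12)))
        d = hierarchical_cluster(x, x.gene_ids)
        heights = d.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_newick_has_all_leaves(self):
        rng = np.random.default_rng(11)
        x = _expr(rng.gamma(2, 2, (5, 6)))
        nwk = hierarchical_cluster(x, x.gene_ids).to_newick()
        assert nwk.endswith(";") and all(c in nwk for c in x.cell_ids)


class TestClusterConcordance:
    def test_perfect_split(self):
        assert cluster_concordance([1, 1, 2, 2], ["a", "a", "b", "b"]) == 1.0

    def test_single_cluster_majority(self):
        labels = [1] * 100
        groups = ["a"] * 60 + ["b"] * 40
        assert cluster_concordance(labels, groups) == pytest.approx(0.6)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(12)
        groups = ["a"] * 100 + ["b"] * 100
        purities = []
        for _ in range(20):
            labels = rng.integers(0, 2, 200)
            purities.append(cluster_concordance(list(labels), groups))
        assert 0.5 <= np.mean(purities) <= 0.6

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cluster_concordance([1, 2], ["a"])
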