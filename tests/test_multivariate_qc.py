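"""PCA against brute-force eigen oracles, biplot scaling, clustering vs scipy."""

import numpy as np
import pytest
from scipy.cluster import hierarchy as scipy_hier
from scipy.spatial.distance import pdist

from moringa_qc import biplot_coords, hclust, pca
from moringa_qc.errors import DegenerateDesignError, InsufficientDataError, ValidationError


def power_iteration_eigs(C, n_iter=5000, tol=1e-14):
    """Brute-force dominant-eigenpair extraction with deflation."""
    C = C.copy()
    values = []
    for _ in range(C.shape[0]):
        v = np.ones(C.shape[0]) / np.sqrt(C.shape[0])
        lam = 0.0
        for _ in range(n_iter):
            w = C @ v
            norm = np.linalg.norm(w)
            if norm < tol:
                break
            v_new = w / norm
            lam_new = v_new @ C @ v_new
            if abs(lam_new - lam) < tol:
                v, lam = v_new, lam_new
                break
            v, lam = v_new, lam_new
        values.append(lam)
        C = C - lam * np.outer(v, v)
    return np.array(sorted(values, reverse=True))


class TestPca:
    def test_rank_one_data_has_unit_pc1(self):
        t = np.linspace(0, 1, 8)
        X = np.outer(t, [1.0, -2.0, 0.5])
        result = pca(X, preprocessing="covariance")
        assert result.explained_variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_eigenvalues_match_power_iteration_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(4, 3)) @ np.diag([3.0, 1.0, 0.3])
        result = pca(X, preprocessing="covariance")
        Xc = X - X.mean(0)
        oracle = power_iteration_eigs(Xc.T @ Xc / (X.shape[0] - 1))
        assert result.eigenvalues == pytest.approx(oracle, abs=1e-8)

    def test_matches_sklearn_cross_check(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(9)
        X = rng.normal(size=(20, 6))
        result = pca(X, preprocessing="covariance")
        ref = sklearn.PCA().fit(X)
        assert result.explained_variance_fraction == pytest.approx(ref.explained_variance_ratio_, abs=1e-10)
        assert np.abs(result.loadings.T @ ref.components_.T).diagonal() == pytest.approx(np.ones(6), abs=1e-8)

    def test_fractions_sum_to_one_and_row_permutation_invariant(self, table3):
        X = table3.matrix()
        result = pca(X)
        assert result.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(result.explained_variance_fraction) <= 1e-12)
        perm = np.random.default_rng(0).permutation(X.shape[0])
        assert pca(X[perm]).eigenvalues == pytest.approx(result.eigenvalues, abs=1e-10)

    def test_loadings_orthonormal(self, table3):
        result = pca(table3.matrix())
        gram = result.loadings.T @ result.loadings
        assert gram == pytest.approx(np.eye(gram.shape[0]), abs=1e-10)

    def test_rotation_invariance_of_covariance_eigenvalues(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(15, 4))
        Q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        assert pca(X @ Q, "covariance").eigenvalues == pytest.approx(
            pca(X, "covariance").eigenvalues, abs=1e-9
        )

    def test_sign_convention_deterministic(self, table3):
        a = pca(table3.matrix())
        b = pca(table3.matrix())
        assert np.array_equal(a.loadings, b.loadings)
        for k in range(a.loadings.shape[1]):
            j = np.argmax(np.abs(a.loadings[:, k]))
            assert a.loadings[j, k] > 0

    def test_constant_column_rejected_in_correlation_mode(self):
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        with pytest.raises(DegenerateDesignError):
            pca(X, "correlation")

    def test_published_table_variance_fractions(self, table3):
        """Covariance mode reproduces the reported PC1/PC2 percentages."""
        cov = 100 * pca(table3.matrix(), "covariance").explained_variance_fraction
        assert cov[0] == pytest.approx(30.3, abs=0.5)
        assert cov[1] == pytest.approx(25.1, abs=0.5)


class TestBiplot:
    def test_alpha_one_distance_biplot(self, table3):
        result = pca(table3.matrix())
        sites, arrows = biplot_coords(result, alpha=1.0)
        assert sites == pytest.approx(result.scores[:, :2])
        assert np.linalg.norm(arrows, axis=0) == pytest.approx(np.ones(2))

    def test_alpha_zero_dual_scaling(self, table3):
        result = pca(table3.matrix())
        sites, arrows = biplot_coords(result, alpha=0.0)
        sing = np.sqrt(result.eigenvalues[:2] * (result.n_samples - 1))
        assert arrows == pytest.approx(result.loadings[:, :2] * sing)

    def test_half_split_reconstructs_rank_two_approximation(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(10, 5))
        Xc = X - X.mean(0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        rank2 = U[:, :2] * S[:2] @ Vt[:2]
        result = pca(X, "covariance")
        sites, arrows = biplot_coords(result, alpha=0.5)
        assert sites @ arrows.T == pytest.approx(rank2, abs=1e-8)

    def test_alpha_out_of_range(self, table3):
        with pytest.raises(ValidationError):
            biplot_coords(pca(table3.matrix()), alpha=1.5)


class TestHclust:
    def test_identical_rows_merge_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        tree = hclust(X, ["a", "b", "c"])
        heights = sorted(tree.merge_heights())
        assert heights[0] == 0.0
        assert set(tree.members) == {"a", "b", "c"}

    def test_planted_partition_recovered_at_root(self):
        rng = np.random.default_rng(21)
        a = rng.normal(0, 0.3, size=(6, 4))
        b = rng.normal(8, 0.3, size=(5, 4))
        ids = [f"a{i}" for i in range(6)] + [f"b{i}" for i in range(5)]
        tree = hclust(np.vstack([a, b]), ids, linkage="average")
        left, right = tree.children
        groups = {frozenset(left.members), frozenset(right.members)}
        assert groups == {frozenset(ids[:6]), frozenset(ids[6:])}

    @pytest.mark.parametrize("linkage", ["average", "complete", "ward"])
    def test_heights_ultrametric_along_root_paths(self, table3, linkage):
        tree = hclust(table3.matrix(), table3.sample_ids, linkage=linkage)

        def check(node):
            if node.is_leaf:
                return
            for child in node.children:
                assert child.height <= node.height + 1e-9
                check(child)

        check(tree)

    @pytest.mark.parametrize("linkage", ["average", "single", "complete", "ward"])
    def test_merge_heights_match_scipy(self, table3, linkage):
        X = table3.matrix()
        ours = sorted(hclust(X, table3.sample_ids, linkage=linkage).merge_heights())
        ref = sorted(scipy_hier.linkage(pdist(X), method=linkage)[:, 2])
        assert ours == pytest.approx(ref, abs=1e-8)

    def test_single_linkage_equals_mst_heights(self):
        """Single-linkage merge heights are exactly the MST edge weights."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 3))
        tree = hclust(X, linkage="single")
        import networkx as nx

        G = nx.Graph()
        for i in range(8):
            for j in range(i + 1, 8):
                G.add_edge(i, j, weight=float(np.linalg.norm(X[i] - X[j])))
        mst = sorted(d["weight"] for _, _, d in nx.minimum_spanning_tree(G).edges(data=True))
        assert sorted(tree.merge_heights()) == pytest.approx(mst, abs=1e-10)

    def test_newick_serialisation_parses(self, table3):
        from io import StringIO

        from Bio import Phylo

        tree = hclust(table3.matrix(), table3.sample_ids)
        parsed = Phylo.read(StringIO(tree.to_newick()), "newick")
        assert sorted(t.name for t in parsed.get_terminals()) == sorted(table3.sample_ids)

    def test_nan_rejected(self):
        with pytest.raises(ValidationError):
            hclust(np.array([[1.0, np.nan], [0.0, 1.0]]))
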