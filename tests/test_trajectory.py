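"""Trajectories: embedding, clustering, principal graph, pseudotime,
Moran's I."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import sparse, stats

from flimcyte.trajectory import (EmbeddingConfig, assign_pseudotime,
                                 cluster_cells, embed, knn_weights,
                                 morans_i, principal_graph,
                                 rank_parameters_by_moran, weighted_jaccard)


def edges_to_weights(edges, n):
    w = sparse.lil_matrix((n, n))
    for i, j in edges:
        w[i, j] = w[j, i] = 1.0
    return w.tocsr()


class TestWeightedJaccard:
    def test_identity_is_one(self):
        assert weighted_jaccard([0.3, 0.0, 2.0], [0.3, 0.0, 2.0]) == 1.0

    def test_disjoint_supports_zero(self):
        assert weighted_jaccard([1.0, 0.0], [0.0, 2.0]) == 0.0

    def test_known_value(self):
        # min sum = 1+1 = 2, max sum = 2+3 = 5
        assert weighted_jaccard([1.0, 3.0], [2.0, 1.0]) == pytest.approx(0.4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            weighted_jaccard([-1.0], [1.0])


class TestEmbed:
    def test_separated_classes_stay_separated(self, feature_table):
        """Embedded points of generatively distinct classes exhibit a
        positive silhouette against the class labels."""
        from sklearn.metrics import silhouette_score

        coords = embed(feature_table, EmbeddingConfig(seed=0))
        s = silhouette_score(coords, feature_table["cell_class"])
        assert s > 0.3

    def test_duplicated_rows_embed_together(self, feature_table):
        df = pd.concat([feature_table.iloc[:60]] * 2, ignore_index=True)
        coords = embed(df, EmbeddingConfig(n_neighbors=10, seed=2))
        d = np.linalg.norm(coords[:60] - coords[60:120], axis=1)
        spread = np.linalg.norm(coords - coords.mean(0), axis=1).mean()
        assert np.median(d) < 0.2 * spread

    def test_deterministic_under_seed(self, feature_table):
        df = feature_table.iloc[:80]
        cfg = EmbeddingConfig(n_neighbors=10, seed=5)
        np.testing.assert_array_equal(embed(df, cfg), embed(df, cfg))

    def test_too_few_cells_rejected(self, feature_table):
        with pytest.raises(ValueError):
            embed(feature_table.iloc[:10], EmbeddingConfig(n_neighbors=20))


class TestClusterCells:
    def test_three_blobs_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        X = np.concatenate([rng.normal(c, 0.3, size=(50, 2))
                            for c in ((0, 0), (8, 0), (0, 8))])
        truth = np.repeat([0, 1, 2], 50)
        labels = cluster_cells(X, method="kmeans", k_or_resolution=3, seed=0)
        assert adjusted_rand_score(truth, labels) > 0.95
        labels = cluster_cells(X, method="leiden", k_or_resolution=0.5,
                               seed=0)
        assert adjusted_rand_score(truth, labels) > 0.95

    def test_k_one_single_cluster(self, rng):
        X = rng.normal(size=(30, 2))
        assert np.all(cluster_cells(X, "kmeans", 1) == 0)

    def test_row_permutation_invariance(self, rng):
        X = np.concatenate([rng.normal(c, 0.3, size=(40, 2))
                            for c in ((0, 0), (6, 6))])
        perm = rng.permutation(len(X))
        a = cluster_cells(X, "leiden", 1.0, seed=1)
        b = cluster_cells(X[perm], "leiden", 1.0, seed=1)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(a[perm], b) == 1.0

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_cells(rng.normal(size=(5, 2)), "kmeans", 10)


class TestPrincipalGraph:
    def test_collinear_centroids_form_path(self):
        emb = np.array([[0.0, 0], [0, 0], [5, 0], [5, 0], [10, 0], [10, 0]])
        cid = np.array([0, 0, 1, 1, 2, 2])
        g = principal_graph(emb, cid, disconnect_factor=np.inf)
        assert sorted(g.degree[n] for n in g.nodes) == [1, 1, 2]

    def test_y_shape_has_one_branch_point(self):
        pts = {0: (0, 0), 1: (1, 0), 2: (2, 1), 3: (2, -1)}
        emb = np.array([pts[i] for i in range(4)], dtype=float)
        g = principal_graph(emb, np.arange(4), disconnect_factor=np.inf)
        degrees = sorted(g.degree[n] for n in g.nodes)
        assert degrees == [1, 1, 1, 3]
        assert [n for n in g.nodes if g.degree[n] >= 3] == [1]

    def test_spanning_tree_edge_count(self, rng):
        emb = rng.normal(size=(60, 2))
        cid = rng.integers(0, 7, size=60)
        k = len(np.unique(cid))
        g = principal_graph(emb, cid, disconnect_factor=np.inf)
        assert g.number_of_edges() == k - 1

    def test_long_edges_disconnect(self):
        emb = np.array([[0.0, 0], [1, 0], [2, 0], [50, 0]])
        g = principal_graph(emb, np.arange(4), disconnect_factor=3.0)
        assert nx.number_connected_components(g) == 2


class TestPseudotime:
    def test_cells_at_root_have_zero(self):
        emb = np.array([[0.0, 0], [0, 0], [4, 0], [8, 0]])
        cid = np.array([0, 0, 1, 2])
        g = principal_graph(emb, cid, disconnect_factor=np.inf)
        pt = assign_pseudotime(g, emb, cid, root=0)
        assert pt[0] == 0.0 and pt[1] == 0.0
        assert pt[3] == pytest.approx(8.0)

    def test_linear_clusters_ordered(self, rng):
        centers = [(0, 0), (5, 0), (10, 0)]
        emb = np.concatenate([rng.normal(c, 0.4, size=(30, 2))
                              for c in centers])
        cid = np.repeat([0, 1, 2], 30)
        g = principal_graph(emb, cid, disconnect_factor=np.inf)
        pt = assign_pseudotime(g, emb, cid, root=0)
        assert np.median(pt[:30]) < np.median(pt[30:60]) < np.median(pt[60:])

    def test_rootless_component_flagged_nan(self):
        emb = np.array([[0.0, 0], [1, 0], [50, 0], [51, 0]])
        cid = np.arange(4)
        g = principal_graph(emb, cid, disconnect_factor=2.0)
        pt = assign_pseudotime(g, emb, cid, root=0)
        assert np.isfinite(pt[:2]).all()
        assert np.isnan(pt[2:]).all()

    def test_progression_recovered(self, progression, trajectory_result):
        """Pseudotime on a known 1-D progression correlates with the
        latent coordinate at |Spearman rho| >= 0.8."""
        _, t = progression
        pt = trajectory_result.pseudotime
        ok = np.isfinite(pt)
        assert ok.mean() > 0.8
        rho = stats.spearmanr(t[ok], pt[ok]).statistic
        assert abs(rho) >= 0.8

    def test_nonnegative_zero_at_root(self, trajectory_result):
        pt = trajectory_result.pseudotime
        ok = np.isfinite(pt)
        assert np.all(pt[ok] >= 0)
        assert pt[ok].min() == pytest.approx(0.0, abs=1e-6)


def morans_double_loop(x, w):
    """Independent O(n^2) reference implementation."""
    x = np.asarray(x, float)
    wd = np.asarray(w.todense())
    n = len(x)
    z = x - x.mean()
    num = sum(wd[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / wd.sum()) * num / (z @ z)


class TestMoransI:
    def test_four_cycle_alternating_is_minus_one(self):
        w = edges_to_weights([(0, 1), (1, 2), (2, 3), (3, 0)], 4)
        assert morans_i(np.array([1, -1, 1, -1]), w) == pytest.approx(-1.0)

    def test_path_graph_block_pattern_is_one_third(self):
        w = edges_to_weights([(0, 1), (1, 2), (2, 3)], 4)
        assert morans_i(np.array([1, 1, -1, -1]), w) == pytest.approx(1 / 3)

    def test_constant_values_rejected(self):
        w = edges_to_weights([(0, 1)], 2)
        with pytest.raises(ValueError, match="zero variance"):
            morans_i(np.array([3.0, 3.0]), w)

    def test_matches_double_loop_oracle_exactly(self, rng):
        """Agreement with an independently coded double-loop
        implementation on 50-cell instances."""
        emb = rng.normal(size=(50, 2))
        w = knn_weights(emb, k=6)
        for _ in range(5):
            x = rng.normal(size=50)
            assert morans_i(x, w) == pytest.approx(
                morans_double_loop(x, w), rel=1e-12)

    def test_scale_and_shift_invariant(self, rng):
        emb = rng.normal(size=(40, 2))
        w = knn_weights(emb, k=5)
        x = rng.normal(size=40)
        assert morans_i(x, w) == pytest.approx(morans_i(3.0 * x - 11.0, w))

    def test_weights_have_zero_diagonal_and_symmetry(self, rng):
        w = knn_weights(rng.normal(size=(30, 2)), k=4)
        assert abs(w.diagonal()).max() == 0
        assert (w != w.T).nnz == 0


class TestMoranRanking:
    def test_smooth_parameter_ranked_first(self, rng):
        n = 150
        t = np.linspace(0, 1, n)
        emb = np.c_[10 * t, np.zeros(n)] + rng.normal(0, 0.1, (n, 2))
        df = pd.DataFrame({"smooth": np.sin(2 * t) + rng.normal(0, 0.05, n)})
        for j in range(5):
            df[f"noise{j}"] = rng.normal(size=n)
        ranked = rank_parameters_by_moran(df, emb, columns=list(df.columns))
        assert ranked["parameter"].iloc[0] == "smooth"

    def test_pure_noise_has_small_i(self, rng):
        n = 200
        emb = rng.normal(size=(n, 2))
        w = knn_weights(emb, k=10)
        x = rng.normal(size=n)
        obs = morans_i(x, w)
        null = [morans_i(rng.permutation(x), w) for _ in range(200)]
        assert abs(obs) < 3 * np.std(null) + abs(np.mean(null))

    def test_ranking_invariant_to_affine_rescale(self, rng):
        n = 80
        emb = rng.normal(size=(n, 2))
        df = pd.DataFrame(rng.normal(size=(n, 4)),
                          columns=list("abcd"))
        r1 = rank_parameters_by_moran(df, emb, columns=list("abcd"))
        df2 = df.copy()
        df2["b"] = 100.0 * df2["b"] - 7.0
        r2 = rank_parameters_by_moran(df2, emb, columns=list("abcd"))
        assert r1["parameter"].tolist() == r2["parameter"].tolist()
        np.testing.assert_allclose(r1["morans_i"], r2["morans_i"])

    def test_fad_lifetimes_lead_on_progression(self, progression,
                                               trajectory_result):
        """FAD decay parameters vary most smoothly along the simulated
        reprogramming continuum and occupy the top Moran ranks."""
        ranked = trajectory_result.morans
        top5 = set(ranked["parameter"].iloc[:5])
        assert len(top5 & {"fad_alpha1", "fad_tau1", "fad_tau2", "fad_tau_m",
                           "I_fad", "redox_ratio"}) >= 3
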