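"""PCA, Butina clustering, trustworthiness and the UMAP grid search."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import chemcov.chemspace_viz as viz
from chemcov.chemspace_viz import (
    EmbeddingParams,
    butina_cluster,
    pca_project,
    trustworthiness,
    umap_grid_search,
)


def rand_frame(n, d, seed=0, cols=None):
    rng = np.random.default_rng(seed)
    cols = cols or [f"d{i}" for i in range(d)]
    return pd.DataFrame(rng.normal(size=(n, d)), columns=cols)


class TestPCA:
    def test_two_dim_input_fully_explained(self):
        res = pca_project(rand_frame(50, 2))
        assert res.explained_variance.sum() == pytest.approx(1.0, abs=1e-8)
        assert res.coords.shape == (50, 2)

    def test_loadings_orthonormal(self):
        res = pca_project(rand_frame(100, 8))
        L = res.loadings.to_numpy()
        assert np.allclose(L.T @ L, np.eye(2), atol=1e-8)

    def test_variance_fractions_non_increasing_and_sum_one(self):
        res = pca_project(rand_frame(80, 6))
        ev = res.explained_variance
        assert np.all(np.diff(ev) <= 1e-12)
        assert ev.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all((ev >= 0) & (ev <= 1))

    def test_mean_row_projects_to_origin_under_zscore(self):
        res = pca_project(rand_frame(60, 5))
        assert np.allclose(res.coords.mean(axis=0), 0, atol=1e-10)

    def test_constant_column_dropped(self):
        df = rand_frame(40, 3)
        df["const"] = 7.0
        res = pca_project(df)
        assert res.dropped_columns == ("const",)
        assert "const" not in res.loadings.index

    def test_raw_mode_differs(self):
        df = rand_frame(40, 4)
        df["d0"] *= 1000  # dominant-scale column
        z = pca_project(df, scaling="zscore")
        raw = pca_project(df, scaling="raw")
        assert raw.explained_variance[0] > z.explained_variance[0]
        with pytest.raises(ValueError):
            pca_project(df, scaling="bogus")


class TestButina:
    def test_all_identical_one_cluster(self):
        fps = np.tile(np.array([1, 0, 1, 1], dtype=np.uint8), (5, 1))
        assert butina_cluster(fps).n_clusters == 1

    def test_all_far_apart_singletons(self):
        fps = np.eye(6, 32, dtype=np.uint8)  # pairwise Tanimoto 0
        labeling = butina_cluster(fps, cutoff=0.5)
        assert labeling.n_clusters == 6

    def test_hand_traced_eight_point_fixture(self):
        """Sphere exclusion traced by hand on a synthetic distance matrix.

        Neighbourhoods at cutoff 0.35: 0:{1,2,6}, 1:{0,2,3}, 2:{0,1},
        3:{1}, 4:{5,6}, 5:{4}, 6:{0,4}.  Processing order (count desc,
        index asc): 0 first -> cluster {0,1,2,6}; then 4 -> {4,5};
        3's only neighbour is taken -> singleton {3}.
        """
        far = 0.9
        D = np.full((7, 7), far)
        np.fill_diagonal(D, 0.0)
        pairs = {(0, 1): 0.1, (0, 2): 0.1, (1, 2): 0.1, (1, 3): 0.3,
                 (4, 5): 0.2, (0, 6): 0.3, (4, 6): 0.3}
        for (i, j), d in pairs.items():
            D[i, j] = D[j, i] = d
        labeling = butina_cluster(distance_matrix=D, cutoff=0.35)
        groups = {}
        for i, lab in enumerate(labeling.labels):
            groups.setdefault(lab, set()).add(i)
        assert set(map(frozenset, groups.values())) == {
            frozenset({0, 1, 2, 6}),
            frozenset({4, 5}),
            frozenset({3}),
        }

    def test_members_within_cutoff_of_centroid(self):
        rng = np.random.default_rng(2)
        fps = (rng.random((60, 256)) < 0.1).astype(np.uint8)
        labeling = butina_cluster(fps, cutoff=0.6)
        D = 1.0 - viz._tanimoto_block(fps, fps)
        for c in labeling.centroids:
            members = np.flatnonzero(labeling.labels == labeling.labels[c])
            assert np.all(D[c, members] <= 0.6)

    @pytest.mark.parametrize("seed", [4, 5])
    def test_matches_reference_implementation(self, seed):
        """Cross-check against rdkit's Butina on instances whose outcome is
        not tie-dependent.  The reference breaks neighbour-count ties by
        larger index where we use smaller, so the comparison is on the
        cluster-size distribution."""
        from rdkit.ML.Cluster import Butina as RDButina

        rng = np.random.default_rng(seed)
        pts = rng.random((40, 3))
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        flat = [D[i, j] for i in range(1, 40) for j in range(i)]
        ref = RDButina.ClusterData(flat, 40, 0.4, isDistData=True)
        ours = butina_cluster(distance_matrix=D, cutoff=0.4)
        ref_sizes = sorted(len(c) for c in ref)
        ours_sizes = sorted(
            int((ours.labels == c).sum()) for c in range(ours.n_clusters)
        )
        assert ours_sizes == ref_sizes


def brute_force_trustworthiness(X, E, k):
    """Direct implementation of the rank-based trustworthiness formula."""
    n = X.shape[0]
    DX = np.sqrt(((X[:, None] - X[None]) ** 2).sum(-1))
    DE = np.sqrt(((E[:, None] - E[None]) ** 2).sum(-1))
    total = 0
    for i in range(n):
        orig_order = [j for j in np.argsort(DX[i]) if j != i]
        ranks = {j: r + 1 for r, j in enumerate(orig_order)}
        emb_knn = set([j for j in np.argsort(DE[i]) if j != i][:k])
        orig_knn = set(orig_order[:k])
        for j in emb_knn - orig_knn:
            total += ranks[j] - k
    return 1 - 2 * total / (n * k * (2 * n - 3 * k - 1))


class TestTrustworthiness:
    def test_identity_embedding_is_perfect(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 2))
        assert trustworthiness(X, X, k=5, metric="euclidean") == pytest.approx(1.0)

    @pytest.mark.parametrize("n,k", [(20, 3), (50, 5), (35, 7)])
    def test_equals_brute_force_oracle(self, n, k):
        rng = np.random.default_rng(n + k)
        X = rng.normal(size=(n, 6))
        E = rng.normal(size=(n, 2))
        fast = trustworthiness(X, E, k=k, metric="euclidean")
        assert 0 <= fast <= 1
        assert fast == pytest.approx(brute_force_trustworthiness(X, E, k))

    def test_k_bounds(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError):
            trustworthiness(X, X[:, :2], k=10, metric="euclidean")


def two_cluster_fingerprints(n=120, seed=0):
    rng = np.random.default_rng(seed)
    base = [(rng.random(2048) < 0.05) for _ in range(2)]
    X = np.zeros((n, 2048), dtype=np.uint8)
    labels = np.zeros(n, dtype=int)
    for i in range(n):
        which = i % 2
        labels[i] = which
        X[i] = (base[which] ^ (rng.random(2048) < 0.01)).astype(np.uint8)
    return X, labels


class TestUMAPGridSearch:
    def test_selected_cell_is_argmax_and_deterministic(self):
        X, _ = two_cluster_fingerprints(80, seed=1)
        grid = {"n_neighbors": (3, 10), "min_dist": (0.01,)}
        params, proj, scores = umap_grid_search(X, grid=grid, seed=42)
        best_row = scores.loc[scores["score"].idxmax()]
        assert params.n_neighbors == int(best_row["n_neighbors"])
        assert scores["score"].max() >= scores["score"].min()
        params2, proj2, _ = umap_grid_search(X, grid=grid, seed=42)
        assert params2 == params
        assert np.allclose(proj.coords.to_numpy(), proj2.coords.to_numpy())

    def test_tie_break_prefers_smaller_parameters(self, monkeypatch):
        X, _ = two_cluster_fingerprints(40, seed=2)
        monkeypatch.setattr(viz, "trustworthiness", lambda *a, **k: 0.5)
        params, _, scores = umap_grid_search(
            X, grid={"n_neighbors": (5, 3), "min_dist": (0.25, 0.01)}, seed=42
        )
        assert (params.n_neighbors, params.min_dist) == (3, 0.01)
        assert len(scores) == 4

    def test_single_cell_grid_returned(self):
        X, _ = two_cluster_fingerprints(40, seed=3)
        params, _, scores = umap_grid_search(
            X, grid={"n_neighbors": (5,), "min_dist": (0.1,)}, seed=1
        )
        assert params == EmbeddingParams(5, 0.1, "jaccard", 1)
        assert len(scores) == 1

    def test_planted_clusters_separate_in_embedding(self):
        from sklearn.metrics import silhouette_score

        X, labels = two_cluster_fingerprints(120, seed=4)
        _, proj, _ = umap_grid_search(
            X, grid={"n_neighbors": (3,), "min_dist": (0.01,)}, seed=42
        )
        assert silhouette_score(proj.coords.to_numpy(), labels) > 0

    def test_empty_grid_is_error(self):
        with pytest.raises(ValueError):
            umap_grid_search(
                np.zeros((20, 64), dtype=np.uint8),
                grid={"n_neighbors": (), "min_dist": (0.1,)},
            )
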