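"""Low-dimensional views of the substance universe.

Two complementary projections:

* PCA of the 16 physicochemical descriptors (z-scored per column by default —
  the descriptors mix units, and unscaled PCA is dominated by molecular
  weight), with loadings and explained-variance fractions;
* UMAP of the Morgan fingerprints (Jaccard metric, consistent with Tanimoto
  similarity), with ``n_neighbors`` and ``min_dist`` chosen by a grid search
  scored via trustworthiness against a reference representation.

The grid-search scorer is configurable because "trustworthiness against a
clustering" admits two readings: (a) trustworthiness of the 2D embedding with
respect to the fingerprint space itself (default), or (b) with respect to a
space in which two substances are close iff they share a Butina cluster.
Butina clustering (sphere exclusion at Tanimoto-distance cutoff, default 0.5)
is computed in-package with a deterministic tie rule.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.manifold import trustworthiness as _sk_trustworthiness

from .overlap import _tanimoto_block

logger = logging.getLogger(__name__)

DEFAULT_BUTINA_CUTOFF = 0.5
DEFAULT_UMAP_GRID = {
    "n_neighbors": (2, 3, 5, 10, 15, 30),
    "min_dist": (0.0, 0.01, 0.1, 0.25, 0.5),
}
DEFAULT_SEED = 42


@dataclass(frozen=True)
class EmbeddingParams:
    n_neighbors: int
    min_dist: float
    metric: str = "jaccard"
    seed: int = DEFAULT_SEED


@dataclass
class ProjectionResult:
    coords: pd.DataFrame  # index = substance ids, columns = x, y
    explained_variance: np.ndarray | None = None  # all components, fractions
    loadings: pd.DataFrame | None = None  # descriptor × (PC1, PC2)
    params: EmbeddingParams | None = None
    dropped_columns: tuple[str, ...] = ()


def pca_project(
    descriptors: pd.DataFrame, scaling: str = "zscore"
) -> ProjectionResult:
    """First two principal components of the descriptor matrix.

    ``scaling="zscore"`` (default) standardizes each column; ``"raw"`` uses
    centred but unscaled values.  Constant columns are dropped under z-scoring
    (their scale is undefined) with a warning.
    """
    if scaling not in {"zscore", "raw"}:
        raise ValueError(f"unknown scaling mode {scaling!r}")
    X = descriptors.to_numpy(dtype=float)
    cols = list(descriptors.columns)
    dropped: tuple[str, ...] = ()
    if scaling == "zscore":
        std = X.std(axis=0, ddof=0)
        keep = std > 0
        if not keep.all():
            dropped = tuple(c for c, k in zip(cols, keep) if not k)
            logger.warning("dropping constant descriptor columns: %s", dropped)
            X, cols = X[:, keep], [c for c, k in zip(cols, keep) if k]
            std = std[keep]
        X = (X - X.mean(axis=0)) / std
    else:
        X = X - X.mean(axis=0)

    pca = PCA(n_components=min(X.shape))
    scores = pca.fit_transform(X)
    coords = pd.DataFrame(
        scores[:, :2], index=descriptors.index, columns=["x", "y"]
    )
    loadings = pd.DataFrame(
        pca.components_[:2].T, index=cols, columns=["PC1", "PC2"]
    )
    return ProjectionResult(
        coords=coords,
        explained_variance=pca.explained_variance_ratio_.copy(),
        loadings=loadings,
        dropped_columns=dropped,
    )


@dataclass
class ClusterLabeling:
    labels: np.ndarray  # contiguous cluster ids from 0, centroids first
    cutoff: float
    centroids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


def butina_cluster(
    fingerprints: np.ndarray | None = None,
    cutoff: float = DEFAULT_BUTINA_CUTOFF,
    distance_matrix: np.ndarray | None = None,
) -> ClusterLabeling:
    """Sphere-exclusion (Butina) clustering at a Tanimoto-distance cutoff.

    Candidate centroids are processed by descending neighbour count, ties by
    ascending index, which makes the labelling independent of input row
    order up to that rule.  Each cluster is the centroid plus its not yet
    assigned neighbours; remaining points become singletons ("false
    singletons" keep the classic algorithm's semantics).
    """
    if distance_matrix is None:
        if fingerprints is None:
            raise ValueError("need fingerprints or a distance matrix")
        distance_matrix = 1.0 - _tanimoto_block(fingerprints, fingerprints)
    n = distance_matrix.shape[0]
    within = distance_matrix <= cutoff
    np.fill_diagonal(within, False)
    neighbor_counts = within.sum(axis=1)
    order = sorted(range(n), key=lambda i: (-int(neighbor_counts[i]), i))

    labels = np.full(n, -1, dtype=int)
    centroids = []
    cid = 0
    for i in order:
        if labels[i] != -1:
            continue
        labels[i] = cid
        centroids.append(i)
        members = np.flatnonzero(within[i] & (labels == -1))
        labels[members] = cid
        cid += 1
    return ClusterLabeling(labels=labels, cutoff=cutoff, centroids=np.array(centroids))


def trustworthiness(
    X: np.ndarray, embedding: np.ndarray, k: int = 5, metric: str = "jaccard"
) -> float:
    """Rank-based trustworthiness of a 2D embedding w.r.t. the original space.

    Penalises "intruders": points among the k nearest embedded neighbours that
    are not close in the original space.  1.0 means every embedded
    neighbourhood is faithful.  ``metric`` applies to the original space;
    the embedding is always Euclidean.
    """
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < number of points ({n})")
    Xm = X.astype(bool) if metric == "jaccard" else X
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(
            _sk_trustworthiness(Xm, embedding, n_neighbors=k, metric=metric)
        )


def _cluster_reference_space(labels: np.ndarray) -> np.ndarray:
    """One-hot cluster indicator matrix: Jaccard distance 0 within a cluster,
    1 across clusters — the 'clustering as a space' reading of the scorer."""
    n_clusters = int(labels.max()) + 1
    onehot = np.zeros((labels.size, n_clusters), dtype=bool)
    onehot[np.arange(labels.size), labels] = True
    return onehot


def umap_grid_search(
    fingerprints: np.ndarray,
    grid: dict[str, tuple] | None = None,
    seed: int = DEFAULT_SEED,
    k: int = 5,
    metric: str = "jaccard",
    scorer: str = "fingerprint",
    reference: ClusterLabeling | None = None,
) -> tuple[EmbeddingParams, ProjectionResult, pd.DataFrame]:
    """Grid search over UMAP (n_neighbors, min_dist), scored by trustworthiness.

    ``scorer="fingerprint"`` scores each embedding against the fingerprint
    space; ``scorer="cluster"`` scores against the Butina cluster-indicator
    space (``reference`` required).  The best cell is the argmax score; ties
    break toward smaller n_neighbors, then smaller min_dist.  A cell whose
    embedding fails is scored as missing and excluded.
    """
    import umap  # deferred: heavy import

    grid = grid or DEFAULT_UMAP_GRID
    if not grid["n_neighbors"] or not grid["min_dist"]:
        raise ValueError("grid must be non-empty")
    if scorer == "cluster":
        if reference is None:
            raise ValueError("cluster scorer needs a reference ClusterLabeling")
        X_ref = _cluster_reference_space(reference.labels)
    elif scorer == "fingerprint":
        X_ref = fingerprints.astype(bool)
    else:
        raise ValueError(f"unknown scorer {scorer!r}")

    records = []
    best: tuple[float, int, float] | None = None  # (-score, n_neighbors, min_dist)
    embeddings: dict[tuple[int, float], np.ndarray] = {}
    for n_neighbors in sorted(grid["n_neighbors"]):
        for min_dist in sorted(grid["min_dist"]):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    reducer = umap.UMAP(
                        n_neighbors=n_neighbors,
                        min_dist=min_dist,
                        metric=metric,
                        random_state=seed,
                        n_components=2,
                    )
                    emb = reducer.fit_transform(fingerprints.astype(np.float32))
                score = trustworthiness(X_ref, emb, k=k, metric="jaccard")
            except Exception:
                logger.warning(
                    "UMAP cell failed: n_neighbors=%d min_dist=%s",
                    n_neighbors,
                    min_dist,
                    exc_info=True,
                )
                records.append(
                    {"n_neighbors": n_neighbors, "min_dist": min_dist, "score": np.nan}
                )
                continue
            records.append(
                {"n_neighbors": n_neighbors, "min_dist": min_dist, "score": score}
            )
            embeddings[(n_neighbors, min_dist)] = emb
            key = (-score, n_neighbors, min_dist)
            if best is None or key < best:
                best = key
    scores = pd.DataFrame(records)
    if best is None:
        raise RuntimeError("every grid cell failed to embed")
    _, n_neighbors, min_dist = best
    params = EmbeddingParams(
        n_neighbors=n_neighbors, min_dist=min_dist, metric=metric, seed=seed
    )
    coords = pd.DataFrame(embeddings[(n_neighbors, min_dist)], columns=["x", "y"])
    return params, ProjectionResult(coords=coords, params=params), scores
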