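"""Embedding, clustering, principal-graph pseudotime, and Moran's I.

Cells are embedded with UMAP on min-max-scaled features under a
weighted-Jaccard (Ruzicka) or Euclidean metric, clustered by Leiden
community detection on the neighbor graph (k-means fallback), and
ordered along a principal graph: the Euclidean minimum spanning tree of
cluster centroids with over-long edges removed, which can leave
disconnected components (failed-reprogramming branches).  Pseudotime of
a cell is the geodesic distance along the graph from the root node
(the cluster richest in starting-population EPCs, by default) to the
cell's projection onto the nearest graph edge.  Per-parameter spatial
autocorrelation along the embedding is quantified with Moran's I

    I = (N / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar)
                / sum_i (x_i - xbar)^2,

with binary symmetrized k-nearest-neighbor weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .features import METABOLIC_COLUMNS, NUCLEAR_COLUMNS

__all__ = [
    "EmbeddingConfig",
    "TrajectoryResult",
    "weighted_jaccard",
    "embed",
    "cluster_cells",
    "principal_graph",
    "assign_pseudotime",
    "knn_weights",
    "morans_i",
    "rank_parameters_by_moran",
    "infer_trajectory",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """UMAP settings: 20 neighbors, min_dist 0.3, weighted-Jaccard
    metric on min-max-scaled features, 2 output components."""

    n_neighbors: int = 20
    min_dist: float = 0.3
    metric: str = "weighted_jaccard"
    n_components: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if self.metric not in ("weighted_jaccard", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class TrajectoryResult:
    """Full trajectory output for a cell table."""

    embedding: np.ndarray
    cluster_id: np.ndarray
    graph: nx.Graph
    components: np.ndarray
    root_node: int
    pseudotime: np.ndarray
    branch_points: list[int]
    morans: pd.DataFrame | None = None
    feature_columns: list[str] = field(default_factory=list)


def _feature_matrix(records: pd.DataFrame,
                    columns: list[str] | None) -> tuple[np.ndarray, list[str]]:
    cols = columns or [c for c in METABOLIC_COLUMNS + NUCLEAR_COLUMNS
                       if c in records.columns]
    X = records[cols].to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite; drop or impute NaNs first")
    return X, cols


def _minmax(X: np.ndarray) -> np.ndarray:
    lo = X.min(axis=0, keepdims=True)
    rng = X.max(axis=0, keepdims=True) - lo
    rng[rng == 0] = 1.0
    return (X - lo) / rng


def weighted_jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Ruzicka similarity sum(min)/sum(max) for nonnegative vectors;
    1 for identical nonzero vectors, 0 when supports are disjoint."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("weighted Jaccard requires nonnegative vectors")
    denom = np.maximum(x, y).sum()
    if denom == 0:
        return 1.0
    return float(np.minimum(x, y).sum() / denom)


def _weighted_jaccard_distances(X: np.ndarray) -> np.ndarray:
    """Pairwise 1 - Ruzicka similarity, vectorized."""
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(X[i], X[i + 1:]).sum(axis=1)
        maxs = np.maximum(X[i], X[i + 1:]).sum(axis=1)
        sim = np.where(maxs > 0, mins / np.where(maxs > 0, maxs, 1.0), 1.0)
        d[i, i + 1:] = d[i + 1:, i] = 1.0 - sim
    return d


def embed(
    records: pd.DataFrame,
    cfg: EmbeddingConfig = EmbeddingConfig(),
    columns: list[str] | None = None,
) -> np.ndarray:
    """UMAP embedding of the feature table, deterministic under seed.

    Features are min-max scaled to [0, 1] first; under the
    weighted-Jaccard metric the pairwise distance matrix is precomputed
    (1 - Ruzicka similarity).
    """
    import umap

    X, _ = _feature_matrix(records, columns)
    if len(X) < cfg.n_neighbors + 1:
        raise ValueError("need at least n_neighbors + 1 cells")
    Xs = _minmax(X)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", module="sklearn")
        if cfg.metric == "weighted_jaccard":
            reducer = umap.UMAP(
                n_neighbors=cfg.n_neighbors, min_dist=cfg.min_dist,
                n_components=cfg.n_components, metric="precomputed",
                random_state=cfg.seed)
            return reducer.fit_transform(_weighted_jaccard_distances(Xs))
        reducer = umap.UMAP(
            n_neighbors=cfg.n_neighbors, min_dist=cfg.min_dist,
            n_components=cfg.n_components, metric="euclidean",
            random_state=cfg.seed)
        return reducer.fit_transform(Xs)


def cluster_cells(
    X: np.ndarray,
    method: str = "leiden",
    k_or_resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
) -> np.ndarray:
    """Cluster points (embedding coordinates or features).

    ``leiden`` (default): Leiden community detection on the symmetrized
    k-nearest-neighbor graph, ``k_or_resolution`` acting as the
    resolution parameter.  ``kmeans``: k-means with
    ``k = int(k_or_resolution)`` clusters.  Cluster ids are renumbered
    by first occurrence, so the partition is invariant (up to label
    names) to input row order.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if method == "kmeans":
        k = int(k_or_resolution)
        if k < 1 or k > n:
            raise ValueError("k must be in [1, n]")
        if k == 1:
            return np.zeros(n, dtype=int)
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
    elif method == "leiden":
        import igraph
        import leidenalg

        nn = NearestNeighbors(n_neighbors=min(n_neighbors + 1, n)).fit(X)
        A = nn.kneighbors_graph(X)
        A = A.maximum(A.T).tocoo()
        edges = [(int(i), int(j)) for i, j, v in zip(A.row, A.col, A.data)
                 if i < j and v > 0]
        g = igraph.Graph(n=n, edges=edges)
        part = leidenalg.find_partition(
            g, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=float(k_or_resolution), seed=int(seed))
        labels = np.asarray(part.membership)
    else:
        raise ValueError(f"unknown method {method!r}")
    # renumber by first occurrence for row-order invariance of names
    _, first = np.unique(labels, return_index=True)
    remap = {labels[i]: rank for rank, i in enumerate(np.sort(first))}
    return np.asarray([remap[l] for l in labels], dtype=int)


def principal_graph(
    embedding: np.ndarray,
    cluster_id: np.ndarray,
    disconnect_factor: float = 3.0,
) -> nx.Graph:
    """Principal graph: MST over cluster centroids with long edges cut.

    Edges longer than ``disconnect_factor`` times the median MST edge
    length are removed, possibly splitting the trajectory into
    disconnected components.  Nodes carry their centroid coordinates;
    node ids are cluster ids.  Branch points are nodes of degree >= 3.
    """
    embedding = np.asarray(embedding, dtype=float)
    ids = np.unique(cluster_id)
    cents = np.array([embedding[cluster_id == c].mean(axis=0) for c in ids])
    g = nx.Graph()
    for c, xy in zip(ids, cents):
        g.add_node(int(c), pos=xy)
    if len(ids) < 2:
        return g
    d = np.linalg.norm(cents[:, None] - cents[None, :], axis=-1)
    mst = minimum_spanning_tree(d).tocoo()
    lengths = mst.data
    cutoff = (disconnect_factor * np.median(lengths)
              if np.isfinite(disconnect_factor) else np.inf)
    for i, j, L in zip(mst.row, mst.col, lengths):
        if L <= cutoff:
            g.add_edge(int(ids[i]), int(ids[j]), length=float(L))
    return g


def _branch_points(g: nx.Graph) -> list[int]:
    return sorted(n for n in g.nodes if g.degree[n] >= 3)


def select_root(
    graph: nx.Graph, cluster_id: np.ndarray, labels: np.ndarray,
    root_class: str = "EPC",
) -> int:
    """Default root: the cluster with the highest fraction of
    ``root_class`` cells (ties to the lower cluster id)."""
    best, best_frac = None, -1.0
    for c in sorted(graph.nodes):
        sel = cluster_id == c
        frac = float((labels[sel] == root_class).mean()) if sel.any() else 0.0
        if frac > best_frac:
            best, best_frac = c, frac
    return int(best)


def assign_pseudotime(
    graph: nx.Graph,
    embedding: np.ndarray,
    cluster_id: np.ndarray,
    root: int,
) -> np.ndarray:
    """Geodesic pseudotime from the root node along the principal graph.

    Each cell is projected onto the nearest point of any edge (or node)
    of the graph component it can reach; its pseudotime is the
    along-graph distance from the root to that projection.  Cells whose
    component does not contain the root get NaN (undefined).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty principal graph")
    if root not in graph:
        raise ValueError(f"root node {root} not in graph")
    embedding = np.asarray(embedding, dtype=float)
    node_dist = nx.single_source_dijkstra_path_length(graph, root,
                                                      weight="length")
    pos = nx.get_node_attributes(graph, "pos")
    comp_of = {}
    for ci, comp in enumerate(nx.connected_components(graph)):
        for n in comp:
            comp_of[n] = ci
    root_comp = comp_of[root]

    pt = np.full(len(embedding), np.nan)
    edges = [(u, v, pos[u], pos[v], graph.edges[u, v]["length"])
             for u, v in graph.edges]
    for i, xy in enumerate(embedding):
        best_d2, best_pt = np.inf, np.nan
        # nearest point on any root-component edge or node
        for u, v, pu, pv, L in edges:
            if comp_of[u] != root_comp:
                continue
            seg = pv - pu
            t = 0.0 if L == 0 else float(np.clip(
                np.dot(xy - pu, seg) / (L * L), 0.0, 1.0))
            proj = pu + t * seg
            d2 = float(np.sum((xy - proj) ** 2))
            if d2 < best_d2:
                best_d2 = d2
                best_pt = min(node_dist[u] + t * L,
                              node_dist[v] + (1.0 - t) * L)
        if not edges or not np.isfinite(best_d2):
            # single-node component (or rootless): node fallback
            for n in graph.nodes:
                if comp_of[n] != root_comp:
                    continue
                d2 = float(np.sum((xy - pos[n]) ** 2))
                if d2 < best_d2:
                    best_d2, best_pt = d2, node_dist[n]
        c = int(cluster_id[i])
        if c in comp_of and comp_of[c] != root_comp:
            best_pt = np.nan  # cell's own cluster is unreachable
        pt[i] = best_pt
    return pt


# ---------------------------------------------------------------------------
# Moran's I


def knn_weights(embedding: np.ndarray, k: int = 10) -> sparse.csr_matrix:
    """Binary k-nearest-neighbor spatial weights, symmetrized by max,
    zero diagonal."""
    n = len(embedding)
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(embedding)
    A = nn.kneighbors_graph(embedding)  # includes self link
    A = A.tolil()
    A.setdiag(0)
    A = A.tocsr()
    A = A.maximum(A.T)
    A.eliminate_zeros()
    return A


def morans_i(values: np.ndarray, weights: sparse.spmatrix) -> float:
    """Moran's I spatial autocorrelation of ``values`` under ``weights``.

    Raises on zero variance (undefined statistic).
    """
    x = np.asarray(values, dtype=float)
    w = sparse.csr_matrix(weights)
    if w.shape[0] != w.shape[1] or w.shape[0] != x.size:
        raise ValueError("weights must be n x n for n values")
    if np.abs(w.diagonal()).max() > 0:
        raise ValueError("weight diagonal must be zero")
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        raise ValueError("zero variance: Moran's I undefined")
    W = float(w.sum())
    if W <= 0:
        raise ValueError("total weight must be positive")
    num = float(z @ (w @ z))
    return (x.size / W) * num / denom


def rank_parameters_by_moran(
    records: pd.DataFrame,
    embedding: np.ndarray,
    columns: list[str] | None = None,
    k: int = 10,
) -> pd.DataFrame:
    """Per-parameter Moran's I over the embedding kNN graph, sorted
    descending.  Zero-variance parameters are reported as NaN."""
    X, cols = _feature_matrix(records, columns)
    w = knn_weights(np.asarray(embedding, dtype=float), k=k)
    vals = []
    for j, c in enumerate(cols):
        try:
            vals.append(morans_i(X[:, j], w))
        except ValueError:
            vals.append(np.nan)
    out = pd.DataFrame({"parameter": cols, "morans_i": vals})
    return out.sort_values("morans_i", ascending=False,
                           kind="stable").reset_index(drop=True)


def infer_trajectory(
    records: pd.DataFrame,
    cfg: EmbeddingConfig = EmbeddingConfig(),
    columns: list[str] | None = None,
    cluster_method: str = "leiden",
    k_or_resolution: float = 1.0,
    disconnect_factor: float = 3.0,
    root: int | None = None,
    label_col: str = "cell_class",
    moran_k: int = 10,
) -> TrajectoryResult:
    """End-to-end trajectory inference on a cell table."""
    coords = embed(records, cfg, columns)
    clusters = cluster_cells(coords, method=cluster_method,
                             k_or_resolution=k_or_resolution, seed=cfg.seed)
    g = principal_graph(coords, clusters, disconnect_factor)
    if root is None:
        if label_col in records.columns:
            root = select_root(g, clusters, records[label_col].to_numpy())
        else:
            root = int(min(g.nodes))
    pt = assign_pseudotime(g, coords, clusters, root)
    comp = np.full(len(coords), -1)
    for ci, nodes in enumerate(nx.connected_components(g)):
        for n in nodes:
            comp[clusters == n] = ci
    morans = rank_parameters_by_moran(records, coords, columns, k=moran_k)
    return TrajectoryResult(
        embedding=coords, cluster_id=clusters, graph=g, components=comp,
        root_node=int(root), pseudotime=pt, branch_points=_branch_points(g),
        morans=morans,
        feature_columns=columns or [c for c in METABOLIC_COLUMNS
                                    + NUCLEAR_COLUMNS if c in records.columns])
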