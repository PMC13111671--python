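"""Track-regime clustering and composition statistics.

Tracks are clustered on their z-scored 8-feature vectors: a k-nearest-
neighbour graph under correlation distance (d = 1 − Pearson r between
feature vectors), Leiden community detection at low resolution, and a UMAP
embedding for visualization.  Per-species cluster compositions (percentage
of a species' tracks per cluster) are compared by Euclidean distance, and
a permutation test evaluates whether a focal group's within-cluster
proportions differ from the rest beyond chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin

from .features import FeatureTable, FEATURE_COLUMNS

__all__ = [
    "correlation_distance_matrix",
    "knn_graph",
    "leiden_cluster",
    "umap_embed",
    "cluster_composition",
    "composition_distance_matrix",
    "permutation_proportion_test",
    "cluster_feature_ttests",
    "TrackClusterer",
]


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, FeatureTable):
        return table.feature_matrix()
    return np.asarray(table, dtype=np.float64)


def correlation_distance_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Full pairwise correlation-distance matrix d = 1 − Pearson r.

    Rows with zero variance (correlation undefined) are flagged and their
    distances set to the maximum of the metric (2.0).

    Returns
    -------
    D : (n, n) ndarray
    degenerate : (n,) bool ndarray marking constant rows
    """
    X = np.asarray(X, dtype=np.float64)
    degenerate = X.std(axis=1) < 1e-15
    D = squareform(pdist(X, metric="correlation"))
    if degenerate.any():
        D[degenerate, :] = 2.0
        D[:, degenerate] = 2.0
    np.fill_diagonal(D, 0.0)
    return D, degenerate


def knn_graph(table, n_neighbors: int = 15) -> tuple[ig.Graph, np.ndarray]:
    """Symmetrized (union) k-nearest-neighbour graph under correlation
    distance.

    Returns the igraph graph (edge attribute ``distance``) and the (n, k)
    neighbour-index array before symmetrization.
    """
    X = _as_matrix(table)
    n = len(X)
    if n < n_neighbors + 1:
        raise ValueError(f"need at least n_neighbors+1={n_neighbors + 1} rows, got {n}")
    D, _ = correlation_distance_matrix(X)
    order = np.argsort(D, axis=1, kind="stable")
    # drop self (distance 0 at each row's own index; stable sort may place
    # ties before it, so remove the row index explicitly)
    neigh = np.empty((n, n_neighbors), dtype=np.int64)
    for i in range(n):
        row = order[i]
        row = row[row != i]
        neigh[i] = row[:n_neighbors]
    edges = set()
    for i in range(n):
        for j in neigh[i]:
            edges.add((min(i, int(j)), max(i, int(j))))
    edge_list = sorted(edges)
    g = ig.Graph(n=n, edges=edge_list)
    g.es["distance"] = [D[i, j] for i, j in edge_list]
    return g, neigh


def leiden_cluster(graph: ig.Graph, resolution: float = 0.05, seed: int = 0) -> np.ndarray:
    """Leiden community detection; labels are 1..K with no gaps.

    Uses the resolution-parameterized modularity (RBConfiguration)
    objective on the unweighted graph; deterministic given ``seed``.
    """
    if graph.vcount() == 0:
        raise ValueError("empty graph")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    labels = np.asarray(part.membership, dtype=np.int64)
    # relabel to 1..K in order of first appearance
    _, first_idx = np.unique(labels, return_index=True)
    remap = {old: new + 1 for new, old in enumerate(labels[np.sort(first_idx)])}
    return np.array([remap[v] for v in labels], dtype=np.int64)


def umap_embed(
    table,
    n_neighbors: int = 15,
    min_dist: float = 0.2,
    seed: int = 0,
    metric: str = "correlation",
) -> np.ndarray:
    """2-D UMAP embedding of the feature rows; deterministic given seed."""
    import umap  # deferred: numba compilation is slow at import

    X = _as_matrix(table)
    if len(X) < n_neighbors + 1:
        raise ValueError("too few rows for the requested n_neighbors")
    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        n_components=2,
        metric=metric,
        random_state=seed,
    )
    emb = reducer.fit_transform(X)
    if not np.isfinite(emb).all():
        raise RuntimeError("UMAP produced non-finite coordinates")
    return np.asarray(emb, dtype=np.float64)


def cluster_composition(labels: np.ndarray, species: np.ndarray) -> pd.DataFrame:
    """Per-species percentage of tracks in each cluster.

    Returns a (species × cluster) DataFrame whose rows each sum to 100.
    Species with zero tracks are excluded.
    """
    labels = np.asarray(labels)
    species = np.asarray(species)
    if len(labels) != len(species):
        raise ValueError("labels and species must be aligned per track")
    clusters = np.unique(labels)
    rows = {}
    for sp in pd.unique(species):
        mask = species == sp
        n = mask.sum()
        if n == 0:
            continue
        counts = np.array([(labels[mask] == c).sum() for c in clusters], dtype=float)
        rows[sp] = 100.0 * counts / n
    return pd.DataFrame.from_dict(rows, orient="index", columns=[f"cluster_{c}" for c in clusters])


def composition_distance_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Euclidean distances between species' percentage profiles."""
    M = profiles.to_numpy(dtype=np.float64)
    D = squareform(pdist(M, metric="euclidean"))
    return pd.DataFrame(D, index=profiles.index, columns=profiles.index)


@dataclass(frozen=True)
class PermutationParams:
    """Settings for the permutation proportion test."""

    n_permutations: int = 1000
    seed: int = 0
    exceedance: str = "strict_greater"  # or "add_one_corrected"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.exceedance not in ("strict_greater", "add_one_corrected"):
            raise ValueError("exceedance must be strict_greater or add_one_corrected")


def permutation_proportion_test(
    labels: np.ndarray,
    group_mask: np.ndarray,
    params: PermutationParams = PermutationParams(),
) -> pd.DataFrame:
    """Permutation test on per-cluster proportion differences.

    For each cluster c the observed statistic is |p_focal(c) − p_rest(c)|,
    the absolute difference of the two groups' within-cluster proportions.
    The null is built from ``n_permutations`` random splits of all tracks
    into two groups of the original sizes; p = #{null > observed} / n_perm
    (the add-one-corrected variant uses (#+1)/(n+1)).

    Returns a DataFrame with one row per cluster: observed statistic,
    p-value and null-distribution summaries.
    """
    labels = np.asarray(labels)
    mask = np.asarray(group_mask, dtype=bool)
    if len(labels) != len(mask):
        raise ValueError("labels and group_mask must be aligned")
    n_focal = int(mask.sum())
    n_rest = int((~mask).sum())
    if n_focal == 0 or n_rest == 0:
        raise ValueError("both groups must be non-empty")

    clusters = np.unique(labels)
    onehot = (labels[:, None] == clusters[None, :]).astype(np.float64)  # (n, K)
    obs = np.abs(onehot[mask].mean(axis=0) - onehot[~mask].mean(axis=0))

    rng = np.random.default_rng(params.seed)
    perms = rng.permuted(
        np.tile(mask, (params.n_permutations, 1)), axis=1
    )  # (n_perm, n) random splits of the original sizes
    counts_focal = perms.astype(np.float64) @ onehot  # (n_perm, K)
    totals = onehot.sum(axis=0)[None, :]
    null = np.abs(counts_focal / n_focal - (totals - counts_focal) / n_rest)

    exceed = (null > obs[None, :]).sum(axis=0)
    if params.exceedance == "strict_greater":
        p = exceed / params.n_permutations
    else:
        p = (exceed + 1) / (params.n_permutations + 1)

    return pd.DataFrame(
        {
            "cluster": clusters,
            "observed": obs,
            "p_value": p,
            "null_mean": null.mean(axis=0),
            "null_q95": np.quantile(null, 0.95, axis=0),
        }
    )


def cluster_feature_ttests(
    table, labels: np.ndarray, feature_names: list[str] | None = None
) -> pd.DataFrame:
    """Welch two-sample t-tests, cluster-vs-rest, for every feature.

    Returns one row per (cluster, feature) with the t statistic, two-sided
    p-value and group sizes; degenerate comparisons (a group with < 2 rows,
    or zero variance in both groups) are flagged with NaN statistics.
    """
    if isinstance(table, FeatureTable):
        X = table.feature_matrix()
        names = feature_names or FEATURE_COLUMNS
    else:
        X = np.asarray(table, dtype=np.float64)
        names = feature_names or [f"f{j}" for j in range(X.shape[1])]
    labels = np.asarray(labels)
    rows = []
    for c in np.unique(labels):
        in_c = labels == c
        n1, n2 = int(in_c.sum()), int((~in_c).sum())
        for j, name in enumerate(names):
            a, b = X[in_c, j], X[~in_c, j]
            degenerate = n1 < 2 or n2 < 2 or (a.std() == 0 and b.std() == 0)
            if degenerate:
                t, p = np.nan, np.nan
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            rows.append(
                {
                    "cluster": c,
                    "feature": name,
                    "t": float(t),
                    "p_value": float(p),
                    "n_cluster": n1,
                    "n_rest": n2,
                    "degenerate": bool(degenerate),
                }
            )
    return pd.DataFrame(rows)


class TrackClusterer(ClusterMixin, BaseEstimator):
    """Correlation-kNN + Leiden clustering with a UMAP embedding.

    Parameters
    ----------
    n_neighbors : int, default 15
        Neighbours per row in the kNN graph (and in UMAP).
    resolution : float, default 0.05
        Leiden resolution parameter.
    min_dist : float, default 0.2
        UMAP minimum embedding distance.
    compute_embedding : bool, default True
        Skip the (comparatively slow) UMAP step when False.
    random_state : int, default 0

    Attributes
    ----------
    labels_ : (n,) int array of cluster ids 1..K
    embedding_ : (n, 2) UMAP coordinates (None if not computed)
    graph_ : igraph.Graph of the symmetrized kNN graph
    """

    def __init__(
        self,
        n_neighbors: int = 15,
        resolution: float = 0.05,
        min_dist: float = 0.2,
        compute_embedding: bool = True,
        random_state: int = 0,
    ):
        self.n_neighbors = n_neighbors
        self.resolution = resolution
        self.min_dist = min_dist
        self.compute_embedding = compute_embedding
        self.random_state = random_state

    def fit(self, X, y=None) -> "TrackClusterer":
        if self.n_neighbors < 2:
            raise ValueError("n_neighbors must be >= 2")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if not (0 <= self.min_dist < 1):
            raise ValueError("min_dist must be in [0, 1)")
        self.graph_, self.knn_indices_ = knn_graph(X, self.n_neighbors)
        self.labels_ = leiden_cluster(self.graph_, self.resolution, self.random_state)
        self.embedding_ = (
            umap_embed(X, self.n_neighbors, self.min_dist, self.random_state)
            if self.compute_embedding
            else None
        )
        return self
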