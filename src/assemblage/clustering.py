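"""Seeded hierarchical clustering of plots into assemblages.

A hierarchical clustering of ~10^5 plots would need a plot x plot
dissimilarity matrix far beyond memory, so the hierarchy is built on
*k-means seeds*: Lloyd's k-means with a large k first groups plots with
identical or near-identical IV rows; Bray-Curtis dissimilarity is then
computed between the seed centroids, and a size-weighted average-linkage
(UPGMA) agglomeration — Lance-Williams update

    d(i u j, m) = (n_i * d(i, m) + n_j * d(j, m)) / (n_i + n_j)

with leaf weights equal to seed plot counts — reproduces, exactly, the
plain UPGMA hierarchy of the underlying plots whenever seeds are pure
duplicates, and approximates it otherwise.  Cutting the dendrogram at any
level k and propagating seed membership back through the plot -> seed map
yields the plot-level typology.

``SeededAssemblageClustering`` wraps the pipeline as a scikit-learn style
estimator; the module-level functions expose the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SeedSet",
    "Dendrogram",
    "kmeans_seed",
    "bray_curtis",
    "weighted_average_linkage",
    "cut_dendrogram",
    "cut_typology",
    "export_newick",
    "default_n_seeds",
    "SeededAssemblageClustering",
    "MAX_LEAVES",
]

#: Refusal threshold for the agglomeration: beyond this many leaves the
#: dense dissimilarity matrix is the very memory problem seeding exists to
#: solve, so the caller is told to seed harder instead.
MAX_LEAVES = 30_000


@dataclass
class SeedSet:
    """k-means seeds: centroids, plot counts, and the plot -> seed map."""

    centroids: np.ndarray  # (k, S) mean IV per seed
    sizes: np.ndarray  # (k,) plot counts
    plot_to_seed: pd.Series  # index plot_id -> seed index
    species: list

    def __post_init__(self):
        if (self.sizes < 1).any():
            raise ValueError("empty seed")
        if int(self.sizes.sum()) != len(self.plot_to_seed):
            raise ValueError("seed sizes do not sum to the number of plots")

    @property
    def n_seeds(self) -> int:
        return len(self.sizes)


@dataclass
class Dendrogram:
    """Agglomeration history.

    ``merges`` has one row per merge: (left_id, right_id, height,
    merged_plot_count).  Leaves are ids 0..n_leaves-1; merge t creates id
    n_leaves + t.  Heights are non-decreasing (average linkage is monotone).
    """

    merges: np.ndarray  # (n_leaves - 1, 4) float
    n_leaves: int
    leaf_sizes: np.ndarray

    def __post_init__(self):
        if self.merges.shape != (self.n_leaves - 1, 4):
            raise ValueError("dendrogram must contain exactly n_leaves - 1 merges")
        h = self.merges[:, 2]
        if np.any(np.diff(h) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def default_n_seeds(n_plots: int) -> int:
    """Default seeding k: min(20000, ceil(n_plots / 6)).

    20 000 seeds is the scale used for national inventories (~1.3e5 plots);
    smaller runs scale the seed count down proportionally.
    """
    return int(min(20_000, -(-n_plots // 6)))


def _as_matrix(ivm):
    if isinstance(ivm, pd.DataFrame):
        return (
            ivm.to_numpy(dtype=float),
            [str(p) for p in ivm.index],
            [str(s) for s in ivm.columns],
        )
    X = np.asarray(ivm, dtype=float)
    return X, [str(i) for i in range(X.shape[0])], [str(j) for j in range(X.shape[1])]


def kmeans_seed(
    ivm,
    k: int,
    n_start: int = 5,
    max_iter: int = 100,
    rng_seed: int | None = 0,
) -> SeedSet:
    """Euclidean Lloyd k-means on IV rows; best of ``n_start`` restarts by
    within-cluster sum of squares.

    Centroids are recomputed as exact means of the final assignment and
    empty seeds (possible only in pathological cases) are dropped, so the
    SeedSet invariants hold regardless of convergence.
    """
    X, plot_ids, species = _as_matrix(ivm)
    n_distinct = len(np.unique(X, axis=0))
    if k > n_distinct:
        raise ValueError(
            f"k={k} exceeds the {n_distinct} distinct IV rows; choose a smaller k"
        )
    km = KMeans(
        n_clusters=k,
        n_init=n_start,
        max_iter=max_iter,
        algorithm="lloyd",
        random_state=rng_seed,
    ).fit(X)
    labels = km.labels_
    present = np.unique(labels)
    remap = {old: new for new, old in enumerate(present)}
    labels = np.array([remap[l] for l in labels])
    k_eff = len(present)
    sizes = np.bincount(labels, minlength=k_eff)
    centroids = np.zeros((k_eff, X.shape[1]))
    np.add.at(centroids, labels, X)
    centroids /= sizes[:, None]
    return SeedSet(
        centroids=centroids,
        sizes=sizes,
        plot_to_seed=pd.Series(labels, index=pd.Index(plot_ids, name="plot_id")),
        species=species,
    )


def bray_curtis(matrix) -> np.ndarray:
    """Condensed Bray-Curtis dissimilarity, d(u,v) = sum|u-v| / sum(u+v)."""
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative entries")
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero row: Bray-Curtis undefined")
    return pdist(X, metric="braycurtis")


def weighted_average_linkage(d, sizes) -> Dendrogram:
    """Size-weighted UPGMA on a (condensed or square) dissimilarity matrix.

    Leaf weights are the seed plot counts, so merge heights equal plain
    UPGMA on the fully expanded plot-level matrix when seeds are exact
    duplicates.  Ties are broken by the smallest active index pair, making
    the dendrogram reproducible.
    """
    d = np.asarray(d, dtype=float)
    D = squareform(d) if d.ndim == 1 else d.copy().astype(float)
    n = D.shape[0]
    sizes = np.asarray(sizes, dtype=float)
    if sizes.shape != (n,):
        raise ValueError("sizes must align with the dissimilarity matrix labels")
    if (sizes < 1).any():
        raise ValueError("every leaf weight must be >= 1")
    if n > MAX_LEAVES:
        raise ValueError(
            f"{n} leaves exceeds the {MAX_LEAVES}-leaf guard; "
            "increase k-means seeding to reduce the matrix"
        )
    leaf_sizes = sizes.copy()
    w = sizes.copy()
    np.fill_diagonal(D, np.inf)
    cluster_id = np.arange(n)
    active = np.ones(n, dtype=bool)
    merges = np.empty((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        flat = np.argmin(D)  # first occurrence = smallest (row, col) pair
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        h = D[i, j]
        merges[step] = (
            min(cluster_id[i], cluster_id[j]),
            max(cluster_id[i], cluster_id[j]),
            h,
            w[i] + w[j],
        )
        # Lance-Williams weighted-average update into slot i
        new_row = (w[i] * D[i, :] + w[j] * D[j, :]) / (w[i] + w[j])
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        w[i] += w[j]
        active[j] = False
        cluster_id[i] = next_id
        next_id += 1
    return Dendrogram(merges=merges, n_leaves=n, leaf_sizes=leaf_sizes)


def _components_at(dend: Dendrogram, k: int) -> np.ndarray:
    """Leaf -> component index after the first n_leaves - k merges."""
    n = dend.n_leaves
    parent = np.arange(2 * n - 1)

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - k):
        left, right, _, _ = dend.merges[t]
        new = n + t
        parent[find(int(left))] = new
        parent[find(int(right))] = new
    roots = np.array([find(i) for i in range(n)])
    return roots


def cut_dendrogram(dend: Dendrogram, k: int) -> np.ndarray:
    """Seed-level cluster labels 1..k at cut level k.

    Cluster ids are assigned in order of each cluster's smallest leaf
    index — a stable rule, so memberships are identical across reruns.
    """
    if not 1 <= k <= dend.n_leaves:
        raise ValueError(f"k must lie in [1, {dend.n_leaves}]")
    roots = _components_at(dend, k)
    order: dict = {}
    labels = np.empty(dend.n_leaves, dtype=int)
    for leaf in range(dend.n_leaves):
        r = roots[leaf]
        if r not in order:
            order[r] = len(order) + 1
        labels[leaf] = order[r]
    if len(order) != k:
        raise AssertionError("cut produced wrong number of clusters")
    return labels


def cut_typology(dend: Dendrogram, seedset: SeedSet, k: int) -> pd.Series:
    """Propagate a seed-level cut to plots via the plot -> seed map."""
    seed_labels = cut_dendrogram(dend, k)
    out = seedset.plot_to_seed.map(lambda s: seed_labels[s])
    out.name = "cluster"
    return out


def export_newick(dend: Dendrogram, labels=None) -> str:
    """Ultrametric Newick string; leaf depth below a node = node height / 2."""
    n = dend.n_leaves
    if labels is None:
        labels = [f"S{i}" for i in range(n)]
    height = np.zeros(2 * n - 1)
    children: dict = {}
    for t, (l, r, h, _) in enumerate(dend.merges):
        node = n + t
        height[node] = h
        children[node] = (int(l), int(r))

    def render(node: int) -> str:
        if node < n:
            return str(labels[node])
        l, r = children[node]
        bl = height[node] / 2 - height[l] / 2
        br = height[node] / 2 - height[r] / 2
        return f"({render(l)}:{bl:.10g},{render(r)}:{br:.10g})"

    return render(2 * n - 2) + ";"


class SeededAssemblageClustering(ClusterMixin, BaseEstimator):
    """Seeded Bray-Curtis UPGMA clustering of plot IV rows.

    Parameters
    ----------
    n_clusters : int, default=2
        Cut level used by :meth:`fit_predict` / ``labels_``.
    n_seeds : int or "auto", default="auto"
        Number of k-means seeds; "auto" uses min(20000, ceil(n/6)), capped
        at the number of distinct rows.
    n_start, max_iter : int
        k-means restarts and Lloyd iteration cap.
    random_state : int, default=0
        Seed for the k-means initialisation.

    Attributes
    ----------
    seed_set_ : SeedSet
    dendrogram_ : Dendrogram
    labels_ : ndarray of shape (n_plots,)
        Cluster labels (1..n_clusters) at the requested cut.
    """

    def __init__(self, n_clusters=2, n_seeds="auto", n_start=5, max_iter=100, random_state=0):
        self.n_clusters = n_clusters
        self.n_seeds = n_seeds
        self.n_start = n_start
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        Xa, plot_ids, species = _as_matrix(X)
        if Xa.ndim != 2 or Xa.shape[0] < 2:
            raise ValueError("X must be a 2-D matrix with at least two plots")
        n_distinct = len(np.unique(Xa, axis=0))
        k = self.n_seeds
        if k == "auto":
            k = min(default_n_seeds(Xa.shape[0]), n_distinct)
        self.seed_set_ = kmeans_seed(
            pd.DataFrame(Xa, index=plot_ids, columns=species),
            k=k,
            n_start=self.n_start,
            max_iter=self.max_iter,
            rng_seed=self.random_state,
        )
        self.seed_dissimilarity_ = bray_curtis(self.seed_set_.centroids)
        self.dendrogram_ = weighted_average_linkage(
            self.seed_dissimilarity_, self.seed_set_.sizes
        )
        self.labels_ = self.cut(self.n_clusters).to_numpy()
        self.n_features_in_ = Xa.shape[1]
        return self

    def cut(self, k: int) -> pd.Series:
        """Plot membership (plot_id -> cluster 1..k) at cut level k."""
        check_is_fitted(self, "dendrogram_")
        return cut_typology(self.dendrogram_, self.seed_set_, k)

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
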