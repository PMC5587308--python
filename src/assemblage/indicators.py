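"""Indicator species analysis and typology selection diagnostics.

For a typology with clusters j = 1..k, each species s gets the
Dufrene-Legendre indicator value

    A_sj = mean IV of s over plots of j / sum over j' of that mean
    B_sj = fraction of plots in j where s is present
    IndVal_s = max_j A_sj * B_sj          (0-1 scale)

A is *specificity* (how concentrated the species' mean abundance is in one
cluster), B is *fidelity* (how reliably it appears there).  Significance is
assessed by permuting plot labels: p = (1 + #{IndVal* >= IndVal}) /
(n_perm + 1).

Scanning every cut level of the hierarchy yields four diagnostics per
level — the sum of significant indicator values, the number of significant
indicator species, the mean significant p-value, and the mean (size-
weighted) silhouette width — from which optimal typologies are selected:
first requiring every cluster to have at least one significant indicator,
then flagging global and local optima per index without combining the
indices into a single score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .clustering import Dendrogram, SeedSet, bray_curtis, cut_dendrogram

__all__ = [
    "SelectionConfig",
    "indval",
    "indval_pvalues",
    "silhouette_mean",
    "scan_hierarchy",
    "select_optima",
    "IndicatorSpeciesAnalysis",
    "DIAGNOSTIC_INDICES",
]

#: The four selection indices and their optimisation direction.
DIAGNOSTIC_INDICES = {
    "sum_sig_indval": "max",
    "n_sig_species": "max",
    "mean_sig_p": "min",
    "mean_silhouette": "max",
}


@dataclass(frozen=True)
class SelectionConfig:
    """Typology-scan settings.

    alpha is the significance level for "significant indicator species";
    n_perm the number of label permutations (add-one corrected p-values,
    so min attainable p is 1/(n_perm+1)); k_range the inclusive span of cut
    levels scanned.
    """

    alpha: float = 0.05
    n_perm: int = 999
    k_range: tuple = (2, 200)
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")


def _coerce(ivm, membership):
    if isinstance(ivm, pd.DataFrame):
        X = ivm.to_numpy(dtype=float)
        species = list(map(str, ivm.columns))
        if isinstance(membership, (pd.Series, dict)):
            m = pd.Series(membership).reindex(ivm.index)
            if m.isna().any():
                raise ValueError("membership missing for some plots")
            memb = m.to_numpy()
        else:
            memb = np.asarray(membership)
    else:
        X = np.asarray(ivm, dtype=float)
        species = [str(j) for j in range(X.shape[1])]
        memb = np.asarray(membership)
    if len(memb) != X.shape[0]:
        raise ValueError("membership length must match the number of plots")
    clusters, labels = np.unique(memb, return_inverse=True)
    return X, species, clusters, labels


def _indval_stats(Z, Zpos, starts, counts):
    """IndVal for pre-sorted data: Z rows grouped into contiguous label blocks."""
    sums = np.add.reduceat(Z, starts, axis=0)
    means = sums / counts[:, None]
    tot = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(tot > 0, means / tot, 0.0)
    B = np.add.reduceat(Zpos, starts, axis=0) / counts[:, None]
    ind_mat = A * B
    return ind_mat, ind_mat.max(axis=0), ind_mat.argmax(axis=0)


def _group_blocks(labels):
    order = np.argsort(labels, kind="stable")
    counts = np.bincount(labels)
    if (counts == 0).any():
        raise ValueError("cluster with zero plots")
    starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
    return order, starts, counts.astype(float)


def indval(ivm, membership) -> pd.DataFrame:
    """Indicator values per species: columns indval, cluster, A, B."""
    X, species, clusters, labels = _coerce(ivm, membership)
    order, starts, counts = _group_blocks(labels)
    Z = X[order]
    ind_mat, iv, best = _indval_stats(Z, (Z > 0).astype(float), starts, counts)
    sums = np.add.reduceat(Z, starts, axis=0)
    means = sums / counts[:, None]
    tot = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.where(tot > 0, means / tot, 0.0)
    B = np.add.reduceat((Z > 0).astype(float), starts, axis=0) / counts[:, None]
    cols = np.arange(len(species))
    return pd.DataFrame(
        {
            "indval": iv,
            "cluster": clusters[best],
            "A": A[best, cols],
            "B": B[best, cols],
        },
        index=pd.Index(species, name="species"),
    )


def indval_pvalues(ivm, membership, n_perm: int = 999, rng_seed: int = 0, rng=None) -> pd.DataFrame:
    """IndVal with permutation p-values.

    Plot labels are permuted (equivalently, IV rows are shuffled against the
    fixed membership vector); p = (1 + #{permuted max-IndVal >= observed}) /
    (n_perm + 1), with a 1e-12 slack so exact ties (e.g. species constant
    across plots) count as exceedances.
    """
    X, species, clusters, labels = _coerce(ivm, membership)
    order, starts, counts = _group_blocks(labels)
    Z = X[order]
    _, obs, best = _indval_stats(Z, (Z > 0).astype(float), starts, counts)
    rng = np.random.default_rng(rng_seed) if rng is None else rng
    n = X.shape[0]
    Xpos = (X > 0).astype(float)
    exceed = np.zeros(len(species))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rows = perm[order]
        _, stat, _ = _indval_stats(X[rows], Xpos[rows], starts, counts)
        exceed += stat >= obs - 1e-12
    p = (1.0 + exceed) / (n_perm + 1.0)
    out = indval(ivm, membership)
    out["p_value"] = p
    return out


def silhouette_mean(d, sizes, labels) -> float:
    """Size-weighted mean silhouette width on a seed-level dissimilarity.

    Each seed i carries weight n_i (its plot count).  Treating a seed as
    n_i coincident plots, the within-cluster mean distance is
    a_i = sum_{j in own} n_j d_ij / (N_own - 1) and the neighbour distance
    b_i = min over other clusters of the size-weighted mean; the usual
    s_i = (b_i - a_i) / max(a_i, b_i) is then averaged with weights n_i.
    Seeds alone in their cluster with n_i = 1 get s_i = 0.  With all sizes
    equal to 1 this is the classical silhouette.
    """
    d = np.asarray(d, dtype=float)
    D = squareform(d) if d.ndim == 1 else d
    sizes = np.asarray(sizes, dtype=float)
    labels = np.asarray(labels)
    clusters, lab = np.unique(labels, return_inverse=True)
    k = len(clusters)
    if k < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    G = np.zeros((len(lab), k))
    G[np.arange(len(lab)), lab] = 1.0
    W = sizes @ G  # total plots per cluster
    S = (D * sizes[None, :]) @ G  # S[i, c] = sum_{j in c} n_j d_ij
    own_w = W[lab] - 1.0
    s = np.zeros(len(lab))
    valid = own_w > 0
    a = np.zeros(len(lab))
    a[valid] = S[np.arange(len(lab)), lab][valid] / own_w[valid]
    other = S / W[None, :]
    other[np.arange(len(lab)), lab] = np.inf
    b = other.min(axis=1)
    denom = np.maximum(a, b)
    ok = valid & (denom > 0)
    s[ok] = (b[ok] - a[ok]) / denom[ok]
    return float(np.average(s, weights=sizes))


def scan_hierarchy(ivm, dend: Dendrogram, seedset: SeedSet, cfg: SelectionConfig) -> pd.DataFrame:
    """One diagnostics row per cut level in cfg.k_range.

    Permutations at each level use an independent, reproducible stream
    derived from (cfg.rng_seed, k), so rows do not depend on the scanned
    range.
    """
    if isinstance(ivm, pd.DataFrame):
        ivm = ivm.loc[seedset.plot_to_seed.index]
    seed_idx = seedset.plot_to_seed.to_numpy()
    seed_d = squareform(bray_curtis(seedset.centroids))
    k_lo, k_hi = cfg.k_range
    k_hi = min(k_hi, dend.n_leaves)
    if k_lo < 2:
        raise ValueError("scan starts at k = 2 (silhouette undefined below)")
    rows = []
    for k in range(k_lo, k_hi + 1):
        seed_labels = cut_dendrogram(dend, k)
        memb = seed_labels[seed_idx]
        res = indval_pvalues(
            ivm, memb, n_perm=cfg.n_perm, rng=np.random.default_rng([cfg.rng_seed, k])
        )
        sig = res[res["p_value"] <= cfg.alpha]
        covered = set(sig["cluster"]) >= set(range(1, k + 1))
        rows.append(
            {
                "k": k,
                "sum_sig_indval": float(sig["indval"].sum()),
                "n_sig_species": int(len(sig)),
                "mean_sig_p": float(sig["p_value"].mean()) if len(sig) else np.nan,
                "mean_silhouette": silhouette_mean(seed_d, seedset.sizes, seed_labels),
                "all_clusters_covered": bool(covered),
            }
        )
    return pd.DataFrame(rows).set_index("k")


def select_optima(diag: pd.DataFrame) -> pd.DataFrame:
    """Flag optimal cut levels among those where every cluster has an indicator.

    Within the eligible rows, each of the four indices gets a global-best
    flag and local-optimum flags (strictly better than both neighbouring
    eligible levels; edge levels compare against their single neighbour).
    No scalar combination is imposed: the result ranks levels by how many
    indices flag them, for inspection.
    """
    eligible = diag[diag["all_clusters_covered"]].sort_index()
    if eligible.empty:
        warnings.warn("no cut level has an indicator species in every cluster", stacklevel=2)
        return pd.DataFrame(
            columns=[f"{w}_{i}" for i in DIAGNOSTIC_INDICES for w in ("global_best", "local_opt")]
            + ["n_flagged_indices"]
        )
    out = pd.DataFrame(index=eligible.index)
    for idx, direction in DIAGNOSTIC_INDICES.items():
        v = eligible[idx].to_numpy(dtype=float)
        if direction == "min":
            v = -v
        out[f"global_best_{idx}"] = v == np.nanmax(v)
        left = np.concatenate([[-np.inf], v[:-1]])
        right = np.concatenate([v[1:], [-np.inf]])
        out[f"local_opt_{idx}"] = (v > left) & (v > right)
    flag_cols = [c for c in out.columns if c.startswith(("global_best", "local_opt"))]
    out["n_flagged_indices"] = sum(
        (out[f"global_best_{i}"] | out[f"local_opt_{i}"]).astype(int)
        for i in DIAGNOSTIC_INDICES
    )
    return out.sort_values(["n_flagged_indices"], ascending=False, kind="stable")


class IndicatorSpeciesAnalysis(BaseEstimator):
    """Dufrene-Legendre indicator species analysis as an estimator.

    Parameters
    ----------
    alpha : float, default=0.05
        Significance level used for the ``significant_`` mask.
    n_perm : int, default=999
        Number of plot-label permutations.
    random_state : int, default=0

    Attributes (after ``fit(X, y)`` with y the cluster membership)
    ----------
    indval_ : ndarray (n_species,) — max A*B per species, 0-1 scale
    best_cluster_ : ndarray — cluster attaining the max
    p_values_ : ndarray — permutation p-values
    significant_ : boolean ndarray — p <= alpha
    results_ : DataFrame with all of the above per species
    """

    def __init__(self, alpha=0.05, n_perm=999, random_state=0):
        self.alpha = alpha
        self.n_perm = n_perm
        self.random_state = random_state

    def fit(self, X, y):
        res = indval_pvalues(X, y, n_perm=self.n_perm, rng_seed=self.random_state)
        self.results_ = res
        self.indval_ = res["indval"].to_numpy()
        self.best_cluster_ = res["cluster"].to_numpy()
        self.p_values_ = res["p_value"].to_numpy()
        self.significant_ = self.p_values_ <= self.alpha
        self.n_features_in_ = len(res)
        return self

    def significant_species(self):
        check_is_fitted(self, "results_")
        return self.results_[self.significant_]
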