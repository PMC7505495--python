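"""Cell-type discovery: KNN graph, Infomap partition, cluster merging,
bootstrap quality, and cluster-level count profiles.

Cells are nodes of an undirected graph built by K-nearest-neighbor search
(K = 50, Euclidean distance on the top principal-component scores; the
directed KNN relation is symmetrized by union).  Communities found by the
two-level Infomap map equation are the transcriptomic cell types.  To
counter over-clustering, clusters whose mean expression profiles (over the
``mnr``-selected genes) correlate above a threshold are merged; the
threshold starts at Pearson R = 0.99 and is lowered in 0.01 steps to 0.90,
with mergers resolved inclusively (connected components of the
above-threshold pair graph, so A~B and B~C merge A, B, C even if A!~C).

Cluster quality is assessed by re-clustering 50 random 85% subsamples:
*purity* of a cluster is the mean fraction of its subsampled members that
land in the best-overlapping re-clustered community, *stability* the mean
fraction of its member pairs that stay co-clustered.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.neighbors import NearestNeighbors

from .matrix import ExpressionMatrix, NormalizedMatrix

__all__ = [
    "NeighborGraph",
    "Clustering",
    "ClusterGeneCounts",
    "ClusterQuality",
    "build_knn_graph",
    "infomap_partition",
    "merge_similar_clusters",
    "bootstrap_quality",
    "cluster_profiles",
    "KnnInfomapClusterer",
    "minmax_normalize",
]

EXACT_SEARCH_MAX_CELLS = 20_000
PRESENCE_MIN_CELLS = 10


@dataclass
class NeighborGraph:
    graph: ig.Graph
    cell_ids: pd.Index
    k: int
    metric: str = "euclidean"


@dataclass
class Clustering:
    """Per-cell cluster labels, dense 1..n_clust."""

    labels: pd.Series
    merge_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        uniq = np.unique(self.labels.to_numpy())
        expected = np.arange(1, len(uniq) + 1)
        if not np.array_equal(np.sort(uniq), expected):
            # re-densify
            remap = {old: new for new, old in enumerate(np.sort(uniq), start=1)}
            self.labels = self.labels.map(remap)

    @property
    def n_clust(self) -> int:
        return int(self.labels.max())

    def sizes(self) -> pd.Series:
        return self.labels.value_counts().sort_index()


@dataclass
class ClusterQuality:
    purity: pd.Series
    stability: pd.Series
    n_iter: int
    frac: float


@dataclass
class ClusterGeneCounts:
    """Cluster x gene count summaries.

    ``raw`` is the contingency table N between cluster and gene identity;
    ``normalized`` sums library-normalized expression per cluster; ``mu``
    are per-cluster cell-averaged normalized profiles, ``mu_complement``
    the same average over all other clusters, and ``mu_hat`` the intra-gene
    L1 profile (columns of ``mu`` scaled to sum 1 for expressed genes).
    """

    raw: pd.DataFrame
    normalized: pd.DataFrame
    cell_counts: pd.Series
    mu: pd.DataFrame
    mu_complement: pd.DataFrame
    mu_hat: pd.DataFrame
    present: pd.Series   # per-cluster flag: >= 10 cells


# ---------------------------------------------------------------------

def _knn_edges(x: np.ndarray, k: int, seed: int) -> np.ndarray:
    n = len(x)
    if n <= EXACT_SEARCH_MAX_CELLS:
        nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
        _, idx = nn.kneighbors(x)
    else:  # approximate search for large datasets, seeded for determinism
        from pynndescent import NNDescent

        index = NNDescent(x, n_neighbors=k + 1, random_state=seed)
        idx, _ = index.neighbor_graph
    src = np.repeat(np.arange(n), k)
    dst = idx[:, 1 : k + 1].ravel()  # drop self column
    keep = src != dst                # guard against approximate self hits
    return np.column_stack([src[keep], dst[keep]])


def build_knn_graph(pca_scores: pd.DataFrame, k: int = 50, seed: int = 0) -> NeighborGraph:
    """Undirected simple KNN graph on PCA scores (union symmetrization)."""
    x = np.asarray(pca_scores, float)
    if k >= len(x):
        raise ValueError(f"k={k} must be smaller than the number of cells ({len(x)})")
    edges = _knn_edges(x, k, seed)
    g = ig.Graph(n=len(x), edges=[tuple(e) for e in edges], directed=False)
    g.simplify()
    return NeighborGraph(g, pd.Index(pca_scores.index), k)


def infomap_partition(g: NeighborGraph, seed: int = 0, trials: int = 10) -> Clustering:
    """Two-level Infomap map-equation partition, deterministic per seed."""
    if g.graph.vcount() == 0:
        raise ValueError("empty graph")
    state = _random.Random(seed)
    ig.set_random_number_generator(state)
    try:
        best = None
        for _ in range(trials):
            part = g.graph.community_infomap()
            if best is None or part.codelength < best.codelength:
                best = part
    finally:
        ig.set_random_number_generator(_random)
    labels = pd.Series(np.asarray(best.membership) + 1, index=g.cell_ids, name="cluster")
    return Clustering(labels)


class KnnInfomapClusterer(BaseEstimator, ClusterMixin):
    """Estimator wrapper: KNN graph + Infomap in one ``fit``.

    Attributes after fit: ``labels_`` (1-based), ``graph_``, ``clustering_``.
    """

    def __init__(self, k: int = 50, seed: int = 0, trials: int = 10):
        self.k = k
        self.seed = seed
        self.trials = trials

    def fit(self, pca_scores: pd.DataFrame, y=None):
        self.graph_ = build_knn_graph(pca_scores, self.k, self.seed)
        self.clustering_ = infomap_partition(self.graph_, self.seed, self.trials)
        self.labels_ = self.clustering_.labels.to_numpy()
        return self

    def fit_predict(self, pca_scores: pd.DataFrame, y=None):
        return self.fit(pca_scores).labels_


# ---------------------------------------------------------------------

def _cluster_means(nm: NormalizedMatrix, labels: pd.Series, genes) -> pd.DataFrame:
    sub = nm.restrict_genes(genes)
    x = sub.values
    lab = labels.reindex(sub.cell_ids).to_numpy()
    out = {}
    for c in np.unique(lab):
        mask = lab == c
        out[c] = np.asarray(x[np.flatnonzero(mask)].mean(axis=0)).ravel()
    return pd.DataFrame(out, index=pd.Index(genes)).T


def merge_components(corr: pd.DataFrame, theta: float) -> list[set]:
    """Connected components of the cluster pair graph with R_P > theta.

    This is the inclusive merge rule: transitively linked clusters merge
    even if some pair falls below the threshold.
    """
    nodes = list(corr.index)
    g = ig.Graph(n=len(nodes))
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            if corr.iloc[a, b] > theta:
                g.add_edge(a, b)
    return [
        {nodes[i] for i in comp}
        for comp in g.connected_components()
    ]


def merge_similar_clusters(
    nm: NormalizedMatrix,
    clustering: Clustering,
    genes,
    theta_start: float = 0.99,
    theta_floor: float = 0.90,
    theta_step: float = 0.01,
) -> Clustering:
    """Inclusive theta-scheduled merging of correlated clusters.

    At each threshold from ``theta_start`` down to ``theta_floor`` the
    cluster-mean profiles over ``genes`` are correlated (Pearson), clusters
    joined by R > theta are merged (connected components), and the step
    repeats until stable before the threshold is lowered.
    """
    genes = pd.Index(genes)
    if len(genes) == 0:
        raise ValueError("gene selection for merging is empty")
    labels = clustering.labels.copy()
    history: list = list(clustering.merge_history)
    thetas = np.arange(theta_start, theta_floor - 1e-9, -theta_step)
    for theta in thetas:
        while True:
            uniq = np.unique(labels.to_numpy())
            if len(uniq) < 2:
                break
            means = _cluster_means(nm, labels, genes)
            corr = means.T.corr()
            comps = merge_components(corr, theta)
            merged_any = False
            for comp in comps:
                if len(comp) > 1:
                    tgt = min(comp)
                    labels[labels.isin(comp)] = tgt
                    history.append({"theta": round(float(theta), 10),
                                    "merged": sorted(int(c) for c in comp)})
                    merged_any = True
            if not merged_any:
                break
    return Clustering(labels, merge_history=history)


# ---------------------------------------------------------------------

def bootstrap_quality(
    pca_scores: pd.DataFrame,
    clustering: Clustering,
    n_iter: int = 50,
    frac: float = 0.85,
    k: int = 50,
    seed: int = 0,
) -> ClusterQuality:
    """Per-cluster purity and stability under subsampled re-clustering."""
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    rng = np.random.default_rng(seed)
    orig = clustering.labels
    n = len(pca_scores)
    clusters = np.unique(orig.to_numpy())
    purity = {c: [] for c in clusters}
    stability = {c: [] for c in clusters}
    for it in range(n_iter):
        pos = np.sort(rng.choice(n, size=int(round(frac * n)), replace=False))
        sub = pca_scores.iloc[pos]
        k_eff = min(k, len(sub) - 1)
        g = build_knn_graph(sub, k_eff, seed=seed + it + 1)
        new = infomap_partition(g, seed=seed + it + 1).labels
        old_sub = orig.reindex(sub.index)
        for c in clusters:
            members = new[old_sub == c]
            if len(members) < 2:
                continue
            counts = members.value_counts()
            purity[c].append(counts.iloc[0] / len(members))
            pairs_same = float((counts * (counts - 1) / 2).sum())
            pairs_all = len(members) * (len(members) - 1) / 2
            stability[c].append(pairs_same / pairs_all)
    return ClusterQuality(
        purity=pd.Series({c: float(np.mean(v)) if v else np.nan
                          for c, v in purity.items()}, name="purity"),
        stability=pd.Series({c: float(np.mean(v)) if v else np.nan
                             for c, v in stability.items()}, name="stability"),
        n_iter=n_iter, frac=frac,
    )


# ---------------------------------------------------------------------

def cluster_profiles(
    m: ExpressionMatrix,
    nm: NormalizedMatrix,
    clustering: Clustering,
) -> ClusterGeneCounts:
    """Cluster x gene raw counts, summed normalized expression, and means."""
    labels = clustering.labels.reindex(m.cell_ids)
    if labels.isna().any():
        raise ValueError("clustering does not label every cell of the matrix")
    clusters = np.sort(np.unique(labels.to_numpy()))
    raw_rows, norm_rows, sizes = [], [], []
    for c in clusters:
        pos = np.flatnonzero((labels == c).to_numpy())
        raw_rows.append(np.asarray(m.counts[pos].sum(axis=0)).ravel())
        norm_rows.append(np.asarray(nm.values[pos].sum(axis=0)).ravel())
        sizes.append(len(pos))
    raw = pd.DataFrame(raw_rows, index=clusters, columns=m.gene_ids)
    normd = pd.DataFrame(norm_rows, index=clusters, columns=m.gene_ids)
    sizes = pd.Series(sizes, index=pd.Index(clusters), name="n_cells")
    mu = normd.div(sizes, axis=0)
    tot_norm = normd.sum(axis=0)
    tot_cells = sizes.sum()
    mu_comp = pd.DataFrame(
        {c: (tot_norm - normd.loc[c]) / (tot_cells - sizes[c]) for c in clusters}
    ).T
    colsum = mu.sum(axis=0)
    mu_hat = mu.div(colsum.where(colsum > 0, 1.0), axis=1)
    present = sizes >= PRESENCE_MIN_CELLS
    return ClusterGeneCounts(raw, normd, sizes, mu, mu_comp, mu_hat,
                             present.rename("present"))


def minmax_normalize(df: pd.DataFrame, axis: int = 1) -> pd.DataFrame:
    """Min-max normalization along ``axis`` (constant rows/cols -> 0).

    Used to display expression time courses on a common [0, 1] scale.
    """
    if axis == 0:
        return minmax_normalize(df.T, axis=1).T
    lo = df.min(axis=1)
    span = df.max(axis=1) - lo
    out = df.sub(lo, axis=0).div(span.where(span > 0, 1.0), axis=0)
    return out.where(span > 0, 0.0)
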