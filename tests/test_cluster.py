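import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from scretina import cluster as cl
from scretina import preprocess as pp
from scretina.matrix import NormalizedMatrix


def gaussian_blobs(rng, centers, n_per, sd=0.5, dims=10):
    pts, labels = [], []
    for i, c in enumerate(centers):
        mu = np.zeros(dims)
        mu[: len(c)] = c
        pts.append(rng.normal(mu, sd, size=(n_per, dims)))
        labels += [i] * n_per
    x = np.vstack(pts)
    idx = [f"c{i}" for i in range(len(x))]
    return pd.DataFrame(x, index=idx), np.array(labels)


# ---------------------------------------------------------------------
# KNN graph
# ---------------------------------------------------------------------

def test_equilateral_triangle_with_k1_gives_triangle_free_of_self_edges():
    pts = pd.DataFrame(
        [[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]], index=list("abc"))
    g = cl.build_knn_graph(pts, k=1)
    assert g.graph.vcount() == 3
    assert not any(e.source == e.target for e in g.graph.es)
    assert g.graph.ecount() <= 3


def test_two_far_blobs_give_two_components(rng):
    pts, _ = gaussian_blobs(rng, [(0, 0), (100, 100)], 100)
    g = cl.build_knn_graph(pts, k=5)
    assert len(g.graph.connected_components()) == 2


def test_k_too_large_rejected(rng):
    pts, _ = gaussian_blobs(rng, [(0, 0)], 10)
    with pytest.raises(ValueError, match="k="):
        cl.build_knn_graph(pts, k=10)


def test_no_self_edges_ever(rng):
    pts, _ = gaussian_blobs(rng, [(0, 0), (3, 3)], 50)
    g = cl.build_knn_graph(pts, k=10)
    assert not any(e.source == e.target for e in g.graph.es)


# ---------------------------------------------------------------------
# Infomap
# ---------------------------------------------------------------------

def test_disconnected_cliques_become_two_clusters():
    import igraph as ig

    g = ig.Graph.Full(10) + ig.Graph.Full(10)
    ng = cl.NeighborGraph(g, pd.Index([f"c{i}" for i in range(20)]), k=9)
    part = cl.infomap_partition(ng, seed=0)
    assert part.n_clust == 2
    assert len(set(part.labels.iloc[:10])) == 1


def test_four_gaussians_recovered_with_high_ari(rng):
    pts, truth = gaussian_blobs(rng, [(0, 0), (8, 0), (0, 8), (8, 8)], 100)
    labels = cl.KnnInfomapClusterer(k=15, seed=1).fit_predict(pts)
    assert adjusted_rand_score(truth, labels) >= 0.9


def test_infomap_deterministic_per_seed(rng):
    pts, _ = gaussian_blobs(rng, [(0, 0), (6, 6)], 80)
    a = cl.KnnInfomapClusterer(k=10, seed=5).fit_predict(pts)
    b = cl.KnnInfomapClusterer(k=10, seed=5).fit_predict(pts)
    assert np.array_equal(a, b)


def test_empty_graph_rejected():
    import igraph as ig

    ng = cl.NeighborGraph(ig.Graph(), pd.Index([]), k=1)
    with pytest.raises(ValueError, match="empty"):
        cl.infomap_partition(ng)


# ---------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------

def _nm_from(dense, gene_ids=None):
    dense = np.asarray(dense, float)
    gene_ids = gene_ids or [f"g{j}" for j in range(dense.shape[1])]
    return NormalizedMatrix(
        sp.csr_matrix(dense), pd.Index([f"c{i}" for i in range(len(dense))]),
        pd.Index(gene_ids), kappa_bar=float(dense.sum(axis=1).mean()))


def test_identical_profile_clusters_merge(rng):
    # two clusters drawn from one NB profile must correlate ~1 and merge
    mu = rng.uniform(1, 20, 40)
    x = rng.poisson(mu, size=(400, 40)).astype(float)
    nm = _nm_from(x)
    labels = pd.Series([1] * 200 + [2] * 200, index=nm.cell_ids)
    merged = cl.merge_similar_clusters(nm, cl.Clustering(labels),
                                       nm.gene_ids)
    assert merged.n_clust == 1
    assert merged.merge_history


def test_orthogonal_marker_blocks_never_merge(rng):
    a = np.zeros((100, 40))
    b = np.zeros((100, 40))
    a[:, :20] = rng.poisson(20, size=(100, 20))
    b[:, 20:] = rng.poisson(20, size=(100, 20))
    nm = _nm_from(np.vstack([a, b]))
    labels = pd.Series([1] * 100 + [2] * 100, index=nm.cell_ids)
    merged = cl.merge_similar_clusters(nm, cl.Clustering(labels), nm.gene_ids)
    assert merged.n_clust == 2
    assert not merged.merge_history


def test_inclusive_chain_merging():
    corr = pd.DataFrame(
        [[1.0, 0.95, 0.5], [0.95, 1.0, 0.95], [0.5, 0.95, 1.0]],
        index=[1, 2, 3], columns=[1, 2, 3])
    comps = cl.merge_components(corr, theta=0.90)
    assert comps == [{1, 2, 3}]


def test_single_cluster_returned_unchanged(rng):
    x = rng.poisson(5, size=(50, 10)).astype(float)
    nm = _nm_from(x)
    labels = pd.Series(1, index=nm.cell_ids)
    merged = cl.merge_similar_clusters(nm, cl.Clustering(labels), nm.gene_ids)
    assert merged.n_clust == 1


def test_merging_never_increases_cluster_count(rng):
    x = rng.poisson(10, size=(300, 30)).astype(float)
    nm = _nm_from(x)
    labels = pd.Series(rng.integers(1, 7, 300), index=nm.cell_ids)
    before = cl.Clustering(labels).n_clust
    merged = cl.merge_similar_clusters(nm, cl.Clustering(labels), nm.gene_ids)
    assert merged.n_clust <= before


def test_empty_gene_selection_rejected(rng):
    nm = _nm_from(rng.poisson(5, size=(20, 5)).astype(float))
    labels = pd.Series([1] * 10 + [2] * 10, index=nm.cell_ids)
    with pytest.raises(ValueError, match="empty"):
        cl.merge_similar_clusters(nm, cl.Clustering(labels), [])


# ---------------------------------------------------------------------
# bootstrap quality
# ---------------------------------------------------------------------

def test_separated_clusters_have_high_purity_and_stability(rng):
    pts, truth = gaussian_blobs(rng, [(0, 0), (10, 10), (0, 10)], 80)
    clustering = cl.Clustering(pd.Series(truth + 1, index=pts.index))
    q = cl.bootstrap_quality(pts, clustering, n_iter=10, k=10, seed=0)
    assert (q.purity > 0.9).all()
    assert (q.stability > 0.9).all()
    assert ((q.purity >= 0) & (q.purity <= 1)).all()
    assert ((q.stability >= 0) & (q.stability <= 1)).all()


def test_artificially_fused_cluster_has_half_stability(rng):
    # two well-separated blobs labeled as ONE original cluster: every
    # resample splits them, so pair co-clustering is ~ 0.5 by counting
    pts, _ = gaussian_blobs(rng, [(0, 0), (20, 20)], 100)
    clustering = cl.Clustering(pd.Series(1, index=pts.index))
    q = cl.bootstrap_quality(pts, clustering, n_iter=10, k=10, seed=0)
    assert q.stability.iloc[0] == pytest.approx(0.5, abs=0.05)
    assert q.purity.iloc[0] == pytest.approx(0.5, abs=0.05)


def test_bootstrap_needs_iterations(rng):
    pts, truth = gaussian_blobs(rng, [(0, 0), (5, 5)], 30)
    clustering = cl.Clustering(pd.Series(truth + 1, index=pts.index))
    with pytest.raises(ValueError, match="n_iter"):
        cl.bootstrap_quality(pts, clustering, n_iter=1, k=5)


# ---------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------

def test_profile_conservation_and_mu_hat(clean_normalized):
    m, nm, _, clustering = clean_normalized
    prof = cl.cluster_profiles(m, nm, clustering)
    # N column sums equal per-gene totals of the kept cells
    assert np.array_equal(prof.raw.sum(axis=0).to_numpy(), m.gene_totals)
    expressed = prof.mu.sum(axis=0) > 0
    colsums = prof.mu_hat.loc[:, expressed].sum(axis=0)
    assert np.allclose(colsums.to_numpy(), 1.0, atol=1e-9)
    assert prof.present.all()


def test_single_cluster_mu_hat_is_one(clean_normalized):
    m, nm, _, _ = clean_normalized
    single = cl.Clustering(pd.Series(1, index=m.cell_ids))
    prof = cl.cluster_profiles(m, nm, single)
    expressed = prof.mu.iloc[0] > 0
    assert np.allclose(prof.mu_hat.iloc[0][expressed], 1.0)


def test_presence_flag_requires_ten_cells(clean_normalized):
    m, nm, _, _ = clean_normalized
    labels = pd.Series(1, index=m.cell_ids)
    labels.iloc[:9] = 2
    prof = cl.cluster_profiles(m, nm, cl.Clustering(labels))
    sizes = prof.cell_counts
    assert not prof.present[sizes.idxmin()]
    assert prof.present[sizes.idxmax()]


def test_minmax_normalization_bounds_and_constants():
    df = pd.DataFrame([[1.0, 3.0, 5.0], [2.0, 2.0, 2.0]])
    out = cl.minmax_normalize(df)
    assert out.iloc[0].tolist() == [0.0, 0.5, 1.0]
    assert (out.iloc[1] == 0.0).all()
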