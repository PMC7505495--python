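import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from scretina import preprocess as pp
from scretina import simulate as sim
from scretina.matrix import ExpressionMatrix


def as_matrix(counts, gene_ids=None):
    counts = np.asarray(counts)
    return ExpressionMatrix(
        sp.csr_matrix(counts),
        [f"c{i}" for i in range(counts.shape[0])],
        gene_ids or [f"g{j}" for j in range(counts.shape[1])],
    )


# ---------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------

def test_normalized_rows_sum_to_kappa_bar():
    m = as_matrix([[2, 3, 5], [10, 10, 10]])
    nm = pp.library_normalize(m)
    sums = np.asarray(nm.values.sum(axis=1)).ravel()
    assert np.allclose(sums, m.kappa_bar, rtol=1e-9)


def test_cell_at_average_library_is_unchanged_and_log_example():
    # two cells with totals 10 and 30: kappa_bar = 20
    m = as_matrix([[4, 6, 0], [10, 10, 10]])
    nm = pp.library_normalize(m)
    assert np.asarray(nm.values.sum(axis=1)).ravel() == pytest.approx([20, 20])
    # cell with |Ci| == kappa_bar keeps its values; log2(1+3) = 2
    m2 = as_matrix([[3, 17], [10, 10]])  # totals 20, 20; kappa_bar 20
    nm2 = pp.library_normalize(m2, log=True)
    assert nm2.dense()[0, 0] == pytest.approx(np.log2(4.0))


def test_zero_count_cell_raises_with_id():
    m = as_matrix([[0, 0], [1, 2]])
    with pytest.raises(ValueError, match="c0"):
        pp.library_normalize(m)


def test_target_sum_overrides_scale():
    m = as_matrix([[2, 2], [3, 1]])
    nm = pp.library_normalize(m, target_sum=100.0)
    assert np.allclose(np.asarray(nm.values.sum(axis=1)).ravel(), 100.0)


# ---------------------------------------------------------------------
# gene scores
# ---------------------------------------------------------------------

def test_cov_score_matches_direct_arithmetic():
    # counts (0,0,3,1): mean 1, population sd sqrt(1.5)
    m = as_matrix(np.array([[0], [0], [3], [1]]))
    sel = pp.select_genes(m, "cov", alpha=0.8, n_top=1)
    expected = np.log2(1 + np.sqrt(1.5)) - 0.8 * np.log2(2.0)
    assert sel.scores.iloc[0] == pytest.approx(expected, abs=1e-12)


def test_mnr_score_matches_direct_arithmetic():
    m = as_matrix(np.array([[0], [0], [3], [1]]))
    sel = pp.select_genes(m, "mnr", alpha=0.8)
    expected = np.log2(1 + 3) - 0.8 * np.log2(2.0)  # = 1.2
    assert sel.scores.iloc[0] == pytest.approx(1.2, abs=1e-12)
    assert sel.scores.iloc[0] == pytest.approx(expected, abs=1e-12)


def test_dnr_score_matches_direct_arithmetic_and_selects():
    bulk = pd.DataFrame({"s1": [0.0], "s2": [3.0], "s3": [7.0]}, index=["g"])
    sel = pp.select_genes(bulk, "dnr")
    assert sel.scores["g"] == pytest.approx(
        np.log2(8) - np.log2(1) - 0.25 * np.log2(4), abs=1e-12)
    assert sel.scores["g"] == pytest.approx(2.5, abs=1e-12)
    assert "g" in sel.selected


def test_scores_invariant_to_row_and_column_order(rng):
    counts = rng.integers(0, 20, (30, 8))
    m = as_matrix(counts)
    perm = rng.permutation(30)
    m_shuf = as_matrix(counts[perm])
    for method in ("cov", "mnr"):
        a = pp.select_genes(m, method).scores
        b = pp.select_genes(m_shuf, method).scores
        assert np.allclose(a.to_numpy(), b.to_numpy())
    bulk = pd.DataFrame(rng.integers(0, 50, (10, 5)).astype(float))
    bulk.columns = [f"s{i}" for i in range(5)]
    a = pp.select_genes(bulk, "dnr").scores
    b = pp.select_genes(bulk[["s3", "s0", "s4", "s1", "s2"]], "dnr").scores
    assert np.allclose(a.to_numpy(), b.to_numpy())


def test_empty_selection_warns_not_raises():
    m = as_matrix(np.ones((5, 3), dtype=int))
    with pytest.warns(UserWarning, match="empty"):
        sel = pp.select_genes(m, "mnr", mnr_threshold=4.0)
    assert len(sel.selected) == 0


def test_exclusion_removes_genes_from_selection_only():
    m = as_matrix(np.array([[0, 0], [9, 9], [0, 0], [5, 5]]),
                  gene_ids=["MT-X", "GOOD"])
    sel = pp.select_genes(m, "cov", n_top=2, exclude=pd.Index(["MT-X"]))
    assert list(sel.selected) == ["GOOD"]
    assert "MT-X" in sel.scores.index


# ---------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------

def _normalized(counts):
    m = as_matrix(counts)
    return pp.library_normalize(m, log=True)


def test_pca_collinear_data_has_single_component(rng):
    from scretina.matrix import NormalizedMatrix

    t = rng.uniform(-3, 3, 40)
    base = np.array([5.0, 6.0, 7.0, 8.0])
    direction = np.array([1.0, -0.5, 2.0, 0.3])
    values = base + np.outer(t, direction)  # exactly on a line
    nm = NormalizedMatrix(
        sp.csr_matrix(values), [f"c{i}" for i in range(40)],
        ["g0", "g1", "g2", "g3"], kappa_bar=1.0, log_transformed=True)
    res = pp.compute_pca(nm, n_components=2)
    assert res.explained_variance_ratio[0] > 1 - 1e-9


def test_pca_truncates_when_components_exceed_rank(rng):
    counts = rng.integers(1, 50, (10, 4))
    nm = _normalized(counts)
    with pytest.warns(UserWarning, match="truncating"):
        res = pp.compute_pca(nm, n_components=9)
    assert res.scores.shape[1] == 4


def test_pca_duplicated_rows_get_identical_scores(rng):
    counts = rng.integers(1, 50, (10, 6))
    counts = np.vstack([counts, counts[:1]])
    nm = _normalized(counts)
    res = pp.compute_pca(nm, n_components=3)
    assert np.allclose(res.scores.iloc[0], res.scores.iloc[-1], atol=1e-8)


def test_pca_reconstruction_from_all_components(rng):
    counts = rng.integers(1, 50, (12, 5))
    nm = _normalized(counts)
    res = pp.compute_pca(nm, n_components=5)
    x = nm.dense()
    recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + res.mean_
    assert np.allclose(recon, x, atol=1e-8)


def test_pca_sign_convention_is_deterministic(rng):
    counts = rng.integers(1, 50, (15, 6))
    nm = _normalized(counts)
    a = pp.compute_pca(nm, n_components=4)
    b = pp.compute_pca(nm, n_components=4)
    assert np.allclose(a.scores.to_numpy(), b.scores.to_numpy())
    load = a.loadings.to_numpy()
    peak = np.abs(load).argmax(axis=0)
    assert (load[peak, np.arange(load.shape[1])] > 0).all()


# ---------------------------------------------------------------------
# cell filtering
# ---------------------------------------------------------------------

def test_filter_removes_planted_high_mito_cells(retina_sim):
    _, m, truth = retina_sim
    high, low, diag = pp.filter_cells(m, pool_threshold=400)
    kept = set(high) | set(low)
    removed = np.array([c not in kept for c in truth.cell_ids])
    assert removed[truth.is_damaged].mean() >= 0.9


def test_filter_needs_minimum_cells():
    m = as_matrix(np.ones((50, 5), dtype=int))
    with pytest.raises(ValueError, match="100"):
        pp.filter_cells(m)


def test_identical_cells_fall_back_to_percentile():
    m = as_matrix(np.tile([5, 5, 5, 1], (200, 1)),
                  gene_ids=["g1", "g2", "g3", "MT-1"])
    with pytest.warns(UserWarning, match="falling back"):
        high, low, _ = pp.filter_cells(m, pool_threshold=0)
    # degenerate distribution: nothing beyond the percentile fallback is cut
    assert len(high) + len(low) >= 0.94 * m.n_cells


def test_pool_threshold_strict_inequality():
    rng = np.random.default_rng(1)
    counts = rng.integers(5, 15, (200, 100))
    # force two cells to land exactly at 801 and 800 total
    counts[0] = 0; counts[0, :100] = 8; counts[0, 0] = 9  # 801
    counts[1] = 8  # 800
    m = as_matrix(counts)
    high, low, _ = pp.filter_cells(m, pool_threshold=800)
    assert m.cell_ids[0] in set(high)
    assert m.cell_ids[1] in set(low)


def test_refiltering_is_bounded_by_percentile_fallbacks(retina_sim):
    """A second filtering pass finds no damaged subpopulation: it can trim
    at most the two percentile fallbacks (~5% per criterion)."""
    _, m, _ = retina_sim
    high, low, _ = pp.filter_cells(m, pool_threshold=400)
    kept = high.append(low)
    m2 = m.subset_cells(kept)
    high2, low2, diag2 = pp.filter_cells(m2, pool_threshold=400)
    second_removed = len(kept) - len(high2) - len(low2)
    assert second_removed / len(kept) < 0.11
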