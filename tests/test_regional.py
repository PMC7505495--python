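import warnings

import numpy as np
import pandas as pd
import pytest

from scretina import preprocess as pp
from scretina import regional as rg
from scretina import simulate as sim


@pytest.fixture(scope="module")
def regional_data():
    """Two classes, half foveal cells, 20 regionally shifted genes."""
    cfg = sim.retina_like_config(
        cells_per_cluster=400, seed=4, fovea_fraction=0.5, n_regional=20,
        classes=("rods", "cones"))
    m, truth = sim.simulate_counts(cfg)
    ann = truth.frame()
    per = ann.index[ann.region == "periphery"]
    fov = ann.index[ann.region == "fovea"]
    nm_per = pp.library_normalize(m.subset_cells(per))
    nm_fov = pp.library_normalize(m.subset_cells(fov),
                                  target_sum=nm_per.kappa_bar)
    return cfg, m, ann, nm_per, nm_fov, per, fov


@pytest.fixture(scope="module")
def rod_stats(regional_data):
    _, _, ann, nm_per, nm_fov, per, fov = regional_data
    return rg.regional_stats(
        nm_per, ann.loc[per, "cluster"], nm_fov, ann.loc[fov, "cluster"],
        "rods", seed=0)


@pytest.fixture(scope="module")
def rod_classifier(regional_data, rod_stats):
    _, _, _, nm_per, nm_fov, _, _ = regional_data
    return rg.train_region_classifier(nm_per, nm_fov, rod_stats, seed=0)


# ---------------------------------------------------------------------
# regional statistics
# ---------------------------------------------------------------------

def _constant_region_matrices(per_vals, fov_vals, n=8):
    """Regions where every cell of cluster 'k' has fixed per-gene values."""
    import scipy.sparse as sp

    from scretina.matrix import NormalizedMatrix

    genes = pd.Index([f"g{j}" for j in range(len(per_vals))])

    def build(vals, tag):
        dense = np.vstack([np.tile(vals, (n, 1)),          # cluster k
                           np.tile(np.ones(len(vals)), (n, 1))])  # cluster o
        ids = pd.Index([f"{tag}{i}" for i in range(2 * n)])
        nm = NormalizedMatrix(sp.csr_matrix(dense), ids, genes,
                              kappa_bar=float(np.sum(vals)))
        labels = pd.Series(["k"] * n + ["o"] * n, index=ids)
        return nm, labels

    return build(np.asarray(per_vals, float), "p"), build(
        np.asarray(fov_vals, float), "f")


def test_specificity_index_arithmetic():
    # gene 0: mu_fov=3, mu_per=1 -> 0.5; gene 1: equal means -> 0
    (nm_per, lab_per), (nm_fov, lab_fov) = _constant_region_matrices(
        [1.0, 2.0], [3.0, 2.0])
    st = rg.regional_stats(nm_per, lab_per, nm_fov, lab_fov, "k", seed=0)
    assert st.table.loc["g0", "specificity"] == pytest.approx(0.5)
    assert st.table.loc["g1", "specificity"] == pytest.approx(0.0)


def test_specificity_antisymmetric_under_region_swap(regional_data):
    _, _, ann, nm_per, nm_fov, per, fov = regional_data
    a = rg.regional_stats(nm_per, ann.loc[per, "cluster"], nm_fov,
                          ann.loc[fov, "cluster"], "rods", seed=3,
                          holdout_frac=0.0)
    b = rg.regional_stats(nm_fov, ann.loc[fov, "cluster"], nm_per,
                          ann.loc[per, "cluster"], "rods", seed=3,
                          holdout_frac=0.0)
    ga = a.table["specificity"].dropna()
    gb = b.table["specificity"].dropna()
    common = ga.index.intersection(gb.index)
    assert np.allclose(ga[common], -gb[common], atol=1e-12)
    assert ga.abs().max() <= 1.0


def test_low_expression_gene_never_overexpressed(rod_stats):
    t = rod_stats.table
    low = t[t["mu"] <= 1.0]
    assert not low["overexpressed"].any()


def test_overexpression_criteria_applied(rod_stats):
    t = rod_stats.table
    over = t[t["overexpressed"]]
    assert (over["mu"] > 1.0).all()
    assert (over["mu_complement"] < 10.0).all()
    assert (np.log10(over["mu"] / over["mu_complement"]) > 0.1).all()


def test_mwu_p_only_for_overexpressed_and_in_log_space(rod_stats):
    t = rod_stats.table
    assert t.loc[t["overexpressed"], "log10_p_adj"].notna().all()
    assert t.loc[~t["overexpressed"], "log10_p_adj"].isna().all()
    assert (t["log10_p_adj"].dropna() <= 0).all()


def test_absent_cluster_rejected(regional_data):
    _, _, ann, nm_per, nm_fov, per, fov = regional_data
    with pytest.raises(ValueError, match="absent"):
        rg.regional_stats(nm_per, ann.loc[per, "cluster"], nm_fov,
                          ann.loc[fov, "cluster"], "no-such-type")


# ---------------------------------------------------------------------
# classifier
# ---------------------------------------------------------------------

def test_classifier_recovers_region_on_held_out_cells(
        regional_data, rod_stats, rod_classifier):
    _, _, _, nm_per, nm_fov, _, _ = regional_data
    q = rg._expr_frame(nm_per, rod_stats.holdout_per, rod_classifier.genes_)
    v = rg.evaluate_regional_identity(rod_classifier, nm_per, nm_fov,
                                      rod_stats, q)
    assert v.r2 >= 0.8
    assert v.verdict == "predominantly peripheral"


def test_shuffled_region_labels_destroy_classifier(regional_data):
    cfg, m, ann, _, _, _, _ = regional_data
    rng = np.random.default_rng(8)
    shuffled = ann.copy()
    shuffled["region"] = rng.permutation(shuffled["region"].to_numpy())
    per = shuffled.index[shuffled.region == "periphery"]
    fov = shuffled.index[shuffled.region == "fovea"]
    nm_per = pp.library_normalize(m.subset_cells(per))
    nm_fov = pp.library_normalize(m.subset_cells(fov),
                                  target_sum=nm_per.kappa_bar)
    st = rg.regional_stats(nm_per, shuffled.loc[per, "cluster"], nm_fov,
                           shuffled.loc[fov, "cluster"], "rods", seed=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf = rg.train_region_classifier(nm_per, nm_fov, st, seed=0)
    q = rg._expr_frame(nm_per, st.holdout_per, clf.genes_)
    v = rg.evaluate_regional_identity(clf, nm_per, nm_fov, st, q)
    assert v.r2 <= 0.1


def test_zero_weights_give_zero_scores(rod_classifier, regional_data, rod_stats):
    _, _, _, nm_per, _, _, _ = regional_data
    import copy

    clf = copy.deepcopy(rod_classifier)
    clf.beta_ = np.zeros_like(clf.beta_)
    q = rg._expr_frame(nm_per, rod_stats.holdout_per[:20], clf.genes_)
    assert (clf.score_cells(q) == 0).all()


def test_scores_bounded_in_open_interval(rod_classifier, regional_data, rod_stats):
    _, _, _, nm_per, _, _, _ = regional_data
    q = rg._expr_frame(nm_per, rod_stats.holdout_per, rod_classifier.genes_)
    s = rod_classifier.score_cells(q)
    assert (s.abs() < 1).all()


def test_peripheral_holdout_overlap_matches_percentile_rule(
        regional_data, rod_stats, rod_classifier):
    _, _, _, nm_per, nm_fov, _, _ = regional_data
    q = rg._expr_frame(nm_per, rod_stats.holdout_per, rod_classifier.genes_)
    v = rg.evaluate_regional_identity(rod_classifier, nm_per, nm_fov,
                                      rod_stats, q)
    # query == held-out peripheral cells: ~95% fall under their own 95th pct
    assert v.frac_peripheral_overlap == pytest.approx(0.95, abs=0.05)


def test_half_and_half_query_is_indeterminate(
        regional_data, rod_stats, rod_classifier):
    _, _, _, nm_per, nm_fov, _, _ = regional_data
    qp = rg._expr_frame(nm_per, rod_stats.holdout_per, rod_classifier.genes_)
    qf = rg._expr_frame(nm_fov, rod_stats.holdout_fov, rod_classifier.genes_)
    v = rg.evaluate_regional_identity(rod_classifier, nm_per, nm_fov,
                                      rod_stats, pd.concat([qp, qf]))
    assert v.verdict == "indeterminate"


def test_no_query_cells_rejected(regional_data, rod_stats, rod_classifier):
    _, _, _, nm_per, nm_fov, _, _ = regional_data
    with pytest.raises(ValueError, match="query"):
        rg.evaluate_regional_identity(
            rod_classifier, nm_per, nm_fov, rod_stats,
            pd.DataFrame(columns=rod_classifier.genes_))


# ---------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------

def test_identical_compositions():
    c = pd.Series({"a": 100, "b": 200, "c": 300})
    rs, p = rg.compare_composition(c, c)
    assert rs == pytest.approx(1.0)
    assert p == pytest.approx(1.0)


def test_reversed_compositions_and_significance():
    a = pd.Series({"a": 500, "b": 300, "c": 200})
    b = pd.Series({"a": 200, "b": 300, "c": 500})
    rs, p = rg.compare_composition(a, b)
    assert rs == pytest.approx(-1.0)
    assert p < 0.01


def test_type_exclusion_and_minimum_universe():
    a = pd.Series({"a": 5, "b": 3, "c": 2, "ganglion": 100})
    b = pd.Series({"a": 5, "b": 3, "c": 2, "ganglion": 0})
    rs, _ = rg.compare_composition(a, b, exclude=["ganglion"])
    assert rs == pytest.approx(1.0)
    with pytest.raises(ValueError, match="3"):
        rg.compare_composition(a[:2], b[:2])


# ---------------------------------------------------------------------
# closeness and z-distance
# ---------------------------------------------------------------------

def _gene_frame(rng, n, shift=0.0, n_genes=20):
    x = rng.normal(5.0 + shift, 1.0, size=(n, n_genes)).clip(0)
    cols = [f"g{j}" for j in range(n_genes)]
    return pd.DataFrame(x, columns=cols,
                        index=[f"cell{shift}_{i}" for i in range(n)])


def test_self_closeness_matches_chi2_tail(rng):
    ref = _gene_frame(rng, 2000)
    qry = _gene_frame(rng, 2000)
    rep = rg.closeness_report(ref, qry, genes=ref.columns, seed=0)
    assert rep.pct_within_3sd == pytest.approx(100 * (1 - np.exp(-4.5)), abs=1.5)
    assert rep.pct_within_5sd >= rep.pct_within_3sd


def test_displaced_population_is_never_close(rng):
    ref = _gene_frame(rng, 500)
    qry = _gene_frame(rng, 500, shift=40.0)
    rep = rg.closeness_report(ref, qry, genes=ref.columns, seed=0)
    assert rep.pct_within_3sd == pytest.approx(0.0, abs=0.5)


def test_top_dge_ranking_uses_epsilon_half():
    mu = pd.Series({"a": 10.0, "b": 0.2, "c": 5.0})
    muc = pd.Series({"a": 1.0, "b": 0.1, "c": 5.0})
    dge = np.log10(mu + 0.5) - np.log10(muc + 0.5)
    top = rg.top_dge_genes(mu, muc, n_top=2)
    assert list(top) == list(dge.nlargest(2).index)


def test_zscore_centering_and_shift(rng):
    ref = _gene_frame(rng, 500)
    z_self = rg.zscore_distance(ref, ref)
    assert abs(z_self.mean()) < 0.1
    shifted = ref + 5 * ref.std().mean()
    z_far = rg.zscore_distance(ref, shifted)
    assert z_far.median() > 3


def test_zscore_of_exact_mean_profile_is_negative(rng):
    ref = _gene_frame(rng, 200)
    q = pd.DataFrame([ref.mean()], index=["mean"])
    z = rg.zscore_distance(ref, q)
    assert z.iloc[0] < 0


def test_zscore_degenerate_reference_rejected():
    ref = pd.DataFrame(np.ones((20, 3)), columns=list("abc"))
    with pytest.raises(ValueError, match="MAD"):
        rg.zscore_distance(ref, ref)
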