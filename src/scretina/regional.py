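"""Regional (fovea vs. periphery) character of cell types and
organoid-to-adult comparison.

For a cluster present in both retinal regions, half of its cells are held
out and the rest characterize the cluster: genes are *overexpressed* when
log10(mu_cluster / mu_rest) > 0.1, mu_cluster > 1 and mu_rest < 10
(library-normalized units); each overexpressed gene gets a regional
specificity index (mu_fov - mu_per)/(mu_fov + mu_per) in [-1, 1] and a
Mann-Whitney U p-value (continuity-corrected, Bonferroni-adjusted, kept in
log10 space so extreme values never underflow).

A per-cell region classifier r = tanh(mean(beta * x)) over the
overexpressed genes (x standardized; targets -1 peripheral / +1 foveal;
squared-error loss with L2 weight 1e-3; beta initialized at 10% of the
specificity index) yields held-out R^2 and, applied to organoid cells, an
overlap-percentile verdict: a class is "predominantly peripheral" when
>50% of query scores overlap the held-out peripheral distribution, <10%
the foveal one, and a chi-square test rejects an even split.

Organoid-to-adult closeness: PCA on the top-20 differentially expressed
genes (dge = log10(mu_type + 0.5) - log10(mu_rest + 0.5)), a Gaussian fit
to the adult (PC1, PC2) cloud by graphical lasso, Mahalanobis distances of
organoid cells, and the percentage within 3 or 5 SD.  A robust per-cell
z-distance (MAD-scaled Euclidean distance to the adult mean profile)
serves the same purpose on gene-expression space directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator
from sklearn.covariance import GraphicalLasso
from sklearn.decomposition import PCA

from .matrix import NormalizedMatrix

__all__ = [
    "RegionalStats",
    "RegionClassifier",
    "ClosenessReport",
    "regional_stats",
    "train_region_classifier",
    "evaluate_regional_identity",
    "compare_composition",
    "closeness_report",
    "zscore_distance",
    "MAD_TO_SD",
]

MAD_TO_SD = 1.4826
LOG10_UNDERFLOW = np.log10(1.8e-307)


# ---------------------------------------------------------------------
# regional statistics
# ---------------------------------------------------------------------

@dataclass
class RegionalStats:
    """Per-gene regional statistics of one cluster (train half)."""

    table: pd.DataFrame          # mu_per, mu_fov, mu, mu_complement,
                                 # overexpressed, specificity, log10_p_adj
    train_per: pd.Index
    train_fov: pd.Index
    holdout_per: pd.Index
    holdout_fov: pd.Index
    cluster: object

    @property
    def overexpressed(self) -> pd.Index:
        return self.table.index[self.table["overexpressed"]]


def _mwu_log10p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U log10 p, normal approximation with
    continuity and tie correction; never underflows."""
    n1, n2 = len(x), len(y)
    allv = np.concatenate([x, y])
    ranks = stats.rankdata(allv)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(allv, return_counts=True)
    n = n1 + n2
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return 0.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    # log10 of two-sided tail
    return float((np.log(2.0) + special.log_ndtr(-z)) / np.log(10.0))


def regional_stats(
    nm_per: NormalizedMatrix,
    labels_per: pd.Series,
    nm_fov: NormalizedMatrix,
    labels_fov: pd.Series,
    cluster,
    holdout_frac: float = 0.5,
    seed: int = 0,
    overexpr_log10_ratio: float = 0.1,
    overexpr_min_mu: float = 1.0,
    overexpr_max_complement: float = 10.0,
) -> RegionalStats:
    """Overexpression, specificity, and MWU significance for one cluster.

    ``nm_per`` / ``nm_fov`` are library-normalized matrices of all cells of
    each region (on a common library-size scale), ``labels_*`` the cluster
    labels.  The cluster must have cells in both regions.
    """
    rng = np.random.default_rng(seed)
    genes = nm_per.gene_ids
    if not genes.equals(nm_fov.gene_ids):
        raise ValueError("regional matrices must share a gene universe")

    def split(nm, labels):
        members = labels.index[labels == cluster]
        if len(members) == 0:
            raise ValueError(f"cluster {cluster!r} absent from a region")
        perm = rng.permutation(len(members))
        n_hold = int(round(holdout_frac * len(members)))
        return members[perm[n_hold:]], members[perm[:n_hold]]

    train_per, hold_per = split(nm_per, labels_per)
    train_fov, hold_fov = split(nm_fov, labels_fov)

    def sums(nm, cells):
        pos = nm.cell_ids.get_indexer(cells)
        return np.asarray(nm.values[pos].sum(axis=0)).ravel()

    def complement_sums(nm, labels, cells):
        # all cells not of this cluster, train+holdout alike, region-wise
        others = labels.index[labels != cluster]
        pos = nm.cell_ids.get_indexer(others)
        return np.asarray(nm.values[pos].sum(axis=0)).ravel(), len(others)

    s_per, s_fov = sums(nm_per, train_per), sums(nm_fov, train_fov)
    o_per, n_o_per = complement_sums(nm_per, labels_per, train_per)
    o_fov, n_o_fov = complement_sums(nm_fov, labels_fov, train_fov)

    m_per, m_fov = len(train_per), len(train_fov)
    mu_per = s_per / m_per
    mu_fov = s_fov / m_fov
    mu = (s_per + s_fov) / (m_per + m_fov)
    mu_comp = (o_per + o_fov) / max(n_o_per + n_o_fov, 1)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mu_comp > 0, mu / np.where(mu_comp > 0, mu_comp, 1.0), np.inf)
        over = (np.log10(ratio) > overexpr_log10_ratio) \
            & (mu > overexpr_min_mu) & (mu_comp < overexpr_max_complement)
        denom = mu_fov + mu_per
        spec = np.where(denom > 0, (mu_fov - mu_per) / np.where(denom > 0, denom, 1.0),
                        np.nan)

    # MWU on per-cell normalized expression, overexpressed genes only
    log10p = np.full(len(genes), np.nan)
    pos_per = nm_per.cell_ids.get_indexer(train_per)
    pos_fov = nm_fov.cell_ids.get_indexer(train_fov)
    dense_per = np.asarray(nm_per.values[pos_per].todense())
    dense_fov = np.asarray(nm_fov.values[pos_fov].todense())
    tested = np.flatnonzero(over)
    n_tests = max(len(tested), 1)
    for j in tested:
        lp = _mwu_log10p(dense_fov[:, j], dense_per[:, j])
        lp_adj = min(lp + np.log10(n_tests), 0.0)   # Bonferroni in log space
        log10p[j] = max(lp_adj, LOG10_UNDERFLOW) if lp_adj < LOG10_UNDERFLOW else lp_adj

    table = pd.DataFrame(
        {
            "mu_per": mu_per, "mu_fov": mu_fov, "mu": mu,
            "mu_complement": mu_comp, "overexpressed": over,
            "specificity": spec, "log10_p_adj": log10p,
        },
        index=genes,
    )
    return RegionalStats(table, train_per, train_fov, hold_per, hold_fov, cluster)


# ---------------------------------------------------------------------
# tanh region classifier
# ---------------------------------------------------------------------

class RegionClassifier(BaseEstimator):
    """r = tanh(mean(beta * x)) region score, -1 peripheral / +1 foveal.

    ``fit`` takes per-region cell x gene expression matrices restricted to
    the overexpressed genes.  Data are standardized per gene (means/SDs of
    the combined training set), each region shuffled and trimmed to an
    equal size m <= ``max_per_region``, and beta minimizes
    sum((y - r)^2) + l2 * ||beta||^2 starting from 10% of the specificity
    index.
    """

    def __init__(self, l2: float = 1e-3, max_per_region: int = 1000,
                 max_iter: int = 5000, tol: float = 1e-6, seed: int = 0):
        self.l2 = l2
        self.max_per_region = max_per_region
        self.max_iter = max_iter
        self.tol = tol
        self.seed = seed

    def fit(self, x_per: pd.DataFrame, x_fov: pd.DataFrame,
            specificity: pd.Series):
        if x_per.shape[1] == 0:
            raise ValueError("empty overexpressed gene set")
        rng = np.random.default_rng(self.seed)
        m = min(len(x_per), len(x_fov), self.max_per_region)
        per = x_per.to_numpy(float)[rng.permutation(len(x_per))[:m]]
        fov = x_fov.to_numpy(float)[rng.permutation(len(x_fov))[:m]]
        combined = np.vstack([per, fov])
        self.mean_ = combined.mean(axis=0)
        sd = combined.std(axis=0)
        self.sd_ = np.where(sd > 0, sd, 1.0)
        X = (combined - self.mean_) / self.sd_
        y = np.concatenate([-np.ones(m), np.ones(m)])
        self.genes_ = pd.Index(x_per.columns)
        beta0 = 0.1 * specificity.reindex(self.genes_).fillna(0.0).to_numpy()
        d = X.shape[1]

        def loss_grad(beta):
            u = X @ beta / d
            r = np.tanh(u)
            e = r - y
            loss = float(e @ e + self.l2 * beta @ beta)
            grad = 2.0 * (X.T @ (e * (1.0 - r**2))) / d + 2.0 * self.l2 * beta
            return loss, grad

        res = optimize.minimize(
            loss_grad, beta0, jac=True, method="L-BFGS-B",
            options={"maxiter": self.max_iter, "ftol": self.tol},
        )
        if not res.success:
            warnings.warn(
                f"region classifier did not fully converge (final loss "
                f"{res.fun:.4g}): {res.message}", stacklevel=2)
        self.beta_ = res.x
        self.n_train_per_region_ = m
        return self

    def score_cells(self, x: pd.DataFrame) -> pd.Series:
        """Per-cell region score r in (-1, 1)."""
        if not hasattr(self, "beta_"):
            raise RuntimeError("fit() must be called first")
        xs = (x[self.genes_].to_numpy(float) - self.mean_) / self.sd_
        r = np.tanh(xs @ self.beta_ / len(self.genes_))
        return pd.Series(r, index=x.index, name="region_score")

    def to_json_dict(self) -> dict:
        return {
            "genes": list(map(str, self.genes_)),
            "mean": self.mean_.tolist(),
            "sd": self.sd_.tolist(),
            "beta": self.beta_.tolist(),
            "l2": self.l2,
            "n_train_per_region": int(self.n_train_per_region_),
        }


def _expr_frame(nm: NormalizedMatrix, cells, genes) -> pd.DataFrame:
    pos = nm.cell_ids.get_indexer(cells)
    if (pos < 0).any():
        raise KeyError("cells missing from normalized matrix")
    sub = nm.restrict_genes(genes)
    return pd.DataFrame(
        np.asarray(sub.values[pos].todense()), index=pd.Index(cells), columns=genes
    )


def train_region_classifier(
    nm_per: NormalizedMatrix, nm_fov: NormalizedMatrix, stats_: RegionalStats,
    **kwargs,
) -> RegionClassifier:
    """Fit the tanh classifier on the training halves of both regions."""
    genes = stats_.overexpressed
    if len(genes) == 0:
        raise ValueError("no overexpressed genes to train on")
    x_per = _expr_frame(nm_per, stats_.train_per, genes)
    x_fov = _expr_frame(nm_fov, stats_.train_fov, genes)
    clf = RegionClassifier(**kwargs)
    clf.fit(x_per, x_fov, stats_.table["specificity"])
    return clf


@dataclass
class RegionalVerdict:
    r2: float
    query_scores: pd.Series
    frac_peripheral_overlap: float
    frac_foveal_overlap: float
    n_excluded: int
    chi2_p: float
    verdict: str   # "predominantly peripheral" | "predominantly foveal" | "indeterminate"


def evaluate_regional_identity(
    clf: RegionClassifier,
    nm_per: NormalizedMatrix, nm_fov: NormalizedMatrix,
    stats_: RegionalStats,
    query: pd.DataFrame,
) -> RegionalVerdict:
    """Held-out R^2 plus the overlap-percentile verdict for query cells.

    ``query`` is a cell x gene expression frame (same normalization scale)
    covering the classifier's genes.
    """
    if len(query) == 0:
        raise ValueError("no query cells")
    hold_per = clf.score_cells(_expr_frame(nm_per, stats_.holdout_per, clf.genes_))
    hold_fov = clf.score_cells(_expr_frame(nm_fov, stats_.holdout_fov, clf.genes_))
    scores = pd.concat([hold_per, hold_fov])
    y = np.concatenate([-np.ones(len(hold_per)), np.ones(len(hold_fov))])
    resid = y - scores.to_numpy()
    r2 = float(1.0 - (resid @ resid) / np.sum((y - y.mean()) ** 2))

    q = clf.score_cells(query[clf.genes_])
    p95_per = float(np.percentile(hold_per, 95))
    p5_fov = float(np.percentile(hold_fov, 5))
    qv = q.to_numpy()
    if p5_fov < p95_per:   # mutually overlapping interval: exclude its cells
        excluded = (qv > p5_fov) & (qv < p95_per)
    else:
        excluded = np.zeros(len(qv), bool)
    kept = qv[~excluded]
    if len(kept) == 0:
        raise ValueError("all query cells fall in the mutually overlapping interval")
    per_overlap = kept < p95_per
    fov_overlap = kept > p5_fov
    f_per = float(per_overlap.mean())
    f_fov = float(fov_overlap.mean())
    counts = np.array([per_overlap.sum(), fov_overlap.sum()])
    if counts.sum() == 0:
        chi2_p = 1.0
    else:
        chi2_p = float(stats.chisquare(counts).pvalue)
    if f_per > 0.5 and f_fov < 0.1 and chi2_p < 0.05:
        verdict = "predominantly peripheral"
    elif f_fov > 0.5 and f_per < 0.1 and chi2_p < 0.05:
        verdict = "predominantly foveal"
    else:
        verdict = "indeterminate"
    return RegionalVerdict(r2, q, f_per, f_fov, int(excluded.sum()), chi2_p, verdict)


# ---------------------------------------------------------------------
# composition and closeness
# ---------------------------------------------------------------------

def compare_composition(
    counts_a: pd.Series, counts_b: pd.Series,
    exclude: list | None = None, n_tests: int = 1,
) -> tuple[float, float]:
    """Spearman R_S of per-type proportions and a chi-square p-value.

    The chi-square tests the 2 x n_types contingency table of cell counts;
    the p-value is Bonferroni-multiplied by ``n_tests`` (capped at 1).
    """
    types = counts_a.index.union(counts_b.index)
    if exclude:
        types = types.difference(pd.Index(exclude))
    if len(types) < 3:
        raise ValueError("need >= 3 shared cell types")
    a = counts_a.reindex(types, fill_value=0).to_numpy(float)
    b = counts_b.reindex(types, fill_value=0).to_numpy(float)
    rs = float(stats.spearmanr(a / a.sum(), b / b.sum()).statistic)
    keep = (a + b) > 0
    if a[keep].sum() > 0 and b[keep].sum() > 0:
        chi2_p = float(stats.chi2_contingency(np.vstack([a[keep], b[keep]]))[1])
    else:
        chi2_p = 1.0
    return rs, float(min(chi2_p * n_tests, 1.0))


@dataclass
class ClosenessReport:
    genes: pd.Index                    # top-dge genes used as PCA dimensions
    adult_scores: pd.DataFrame         # adult cells x (PC1, PC2)
    organoid_scores: pd.DataFrame
    mahalanobis: pd.Series             # per organoid cell
    pct_within_3sd: float
    pct_within_5sd: float

    def __post_init__(self) -> None:
        if (self.mahalanobis < 0).any():
            raise ValueError("distances must be nonnegative")


def top_dge_genes(mu: pd.Series, mu_complement: pd.Series, n_top: int = 20,
                  eps: float = 0.5) -> pd.Index:
    """Genes with the largest dge = log10(mu+eps) - log10(mu_comp+eps)."""
    dge = np.log10(mu + eps) - np.log10(mu_complement + eps)
    return dge.nlargest(n_top).index


def closeness_report(
    adult_expr: pd.DataFrame,
    organoid_expr: pd.DataFrame,
    genes: pd.Index | None = None,
    *,
    mu: pd.Series | None = None,
    mu_complement: pd.Series | None = None,
    n_top: int = 20,
    gl_alpha: float = 0.01,
    seed: int = 0,
) -> ClosenessReport:
    """PCA + graphical-lasso Mahalanobis closeness of organoid cells.

    Either pass ``genes`` directly or cluster means ``mu`` /
    ``mu_complement`` for top-dge ranking.  PCA is fit on all adult cells
    of the type plus an equal-size random organoid subsample; the remaining
    organoid cells are projected.  Closeness is the percentage of all
    organoid cells within Mahalanobis distance 3 (and 5) of the 2D
    Gaussian fit to the adult scores.
    """
    if genes is None:
        if mu is None or mu_complement is None:
            raise ValueError("pass genes or (mu, mu_complement)")
        genes = top_dge_genes(mu, mu_complement, n_top)
    if len(adult_expr) < 10 or len(organoid_expr) < 10:
        raise ValueError("need >= 10 adult and >= 10 organoid cells")
    rng = np.random.default_rng(seed)
    a = adult_expr[genes].to_numpy(float)
    o = organoid_expr[genes].to_numpy(float)
    n_sub = len(a)
    if n_sub > len(o):
        warnings.warn(
            "fewer organoid cells than adult cells; subsample reduced to "
            f"{len(o)}", stacklevel=2)
        n_sub = len(o)
    sub = rng.permutation(len(o))[:n_sub]
    pca = PCA(n_components=2, svd_solver="full").fit(np.vstack([a, o[sub]]))
    a_pc = pca.transform(a)
    o_pc = pca.transform(o)
    gl = GraphicalLasso(alpha=gl_alpha).fit(a_pc)
    center = a_pc.mean(axis=0)
    prec = gl.precision_
    diff = o_pc - center
    d = np.sqrt(np.einsum("ij,jk,ik->i", diff, prec, diff))
    dist = pd.Series(d, index=organoid_expr.index, name="mahalanobis")
    return ClosenessReport(
        genes=pd.Index(genes),
        adult_scores=pd.DataFrame(a_pc, index=adult_expr.index, columns=["PC1", "PC2"]),
        organoid_scores=pd.DataFrame(o_pc, index=organoid_expr.index,
                                     columns=["PC1", "PC2"]),
        mahalanobis=dist,
        pct_within_3sd=float(100.0 * (d < 3).mean()),
        pct_within_5sd=float(100.0 * (d < 5).mean()),
    )


def zscore_distance(
    reference_expr: pd.DataFrame, query_expr: pd.DataFrame, genes=None,
) -> pd.Series:
    """Robust z of each query cell's distance to the reference mean profile.

    Euclidean distance over ``genes`` (default: all shared columns) from
    each cell to the reference mean; standardized by the reference cells'
    own distance distribution, with SD estimated as 1.4826 * MAD.
    """
    if genes is None:
        genes = reference_expr.columns
    genes = pd.Index(genes)
    if len(genes) == 0:
        raise ValueError("empty gene set")
    if len(reference_expr) < 10:
        raise ValueError("need >= 10 reference cells")
    ref = reference_expr[genes].to_numpy(float)
    qry = query_expr[genes].to_numpy(float)
    center = ref.mean(axis=0)
    d_ref = np.linalg.norm(ref - center, axis=1)
    mad = np.median(np.abs(d_ref - np.median(d_ref)))
    if mad == 0:
        raise ValueError("degenerate reference: zero MAD of distances")
    sd = MAD_TO_SD * mad
    d_qry = np.linalg.norm(qry - center, axis=1)
    z = (d_qry - d_ref.mean()) / sd
    return pd.Series(z, index=query_expr.index, name="z_distance")
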