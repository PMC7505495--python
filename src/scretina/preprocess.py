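"""Cell filtering, library normalization, gene selection, and PCA.

This is the shared front end of every downstream analysis:

* ``filter_cells`` removes damaged cells by locating an inflection point in
  the LOESS-smoothed rank-size distribution of detected-gene counts (low
  tail) and mitochondrial fraction (high tail), then splits survivors into
  high/low expression pools by total transcript count.
* ``library_normalize`` rescales every cell to the dataset-average library
  size ``kappa_bar``, optionally followed by log2(1+x).
* ``select_genes`` implements three scores used at different stages:
  the trend-adjusted log coefficient of variation (``cov``,
  CoV = log2(1+sigma) - alpha*log2(1+mu), top-n genes), the mean-normalized
  log-range (``mnr`` = log2(1+max-min) - alpha*log2(1+mu), threshold 4.0)
  and the median-normalized range for bulk tables (``dnr`` =
  log2(1+max) - log2(1+min) - 0.25*log2(1+median), threshold 0.5).
* ``compute_pca`` produces mean-centered scores for the top components with
  a deterministic sign convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import ExpressionMatrix, NormalizedMatrix

__all__ = [
    "GeneSelection",
    "PCAScores",
    "FilterDiagnostics",
    "filter_cells",
    "library_normalize",
    "select_genes",
    "compute_pca",
]

#: default high-expression pool thresholds on |Ci|
POOL_THRESHOLD_ADULT = 800
POOL_THRESHOLD_ORGANOID = 400


@dataclass
class GeneSelection:
    method: str
    scores: pd.Series
    selected: pd.Index
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("gene scores must be finite")


@dataclass
class PCAScores:
    scores: pd.DataFrame        # cells x components
    loadings: pd.DataFrame      # genes x components
    explained_variance_ratio: np.ndarray
    mean_: np.ndarray


@dataclass
class FilterDiagnostics:
    gene_cutoff: float
    mito_cutoff: float
    gene_cutoff_fallback: bool
    mito_cutoff_fallback: bool
    n_removed_genes: int
    n_removed_mito: int


def _rank_size_cutoff(
    values: np.ndarray, percentile: float, *, tail: str,
    span: float = 0.3, n_grid: int = 10_000,
) -> tuple[float, bool]:
    """Locate a cutoff on the LOESS-smoothed rank-size curve of ``values``.

    The curve (sorted values vs. rank) is smoothed by LOESS and evaluated
    at ``n_grid`` evenly spaced relative positions; the cutoff is placed at
    the first point past ``percentile`` (walking into the tail) where the
    discrete second difference of the smoothed curve changes sign.  If no
    sign change is found the percentile itself is used (fallback flag set).

    ``tail='low'`` walks from the percentile toward small values (cells
    below the cutoff fail); ``tail='high'`` walks toward large values
    (cells above the cutoff fail).
    """
    order = np.sort(values)
    n = len(order)
    rel = np.linspace(0.0, 1.0, n_grid)
    ranks = np.arange(n) / max(n - 1, 1)
    curve = lowess(order, ranks, frac=span, xvals=rel)
    second = np.diff(curve, 2)  # index i -> curvature at rel[i+1]
    # curvature below numerical tolerance (relative to the curve's value
    # range) counts as flat, not as a sign flip
    tol = max(1e-8 * np.ptp(curve), 1e-12 * np.abs(curve).max(), 1e-300)
    sign = np.where(np.abs(second) > tol, np.sign(second), 0.0)
    start = int(round(percentile * (n_grid - 3)))
    if tail == "low":
        idx_iter = range(start, 0, -1)
    else:
        idx_iter = range(start, len(sign) - 1)
    cut_idx = None
    for i in idx_iter:
        nxt = i - 1 if tail == "low" else i + 1
        if sign[i] != 0 and sign[nxt] != 0 and sign[nxt] != sign[i]:
            cut_idx = nxt
            break
    if cut_idx is None:
        return float(np.quantile(values, percentile)), True
    return float(curve[cut_idx + 1]), False


def filter_cells(
    m: ExpressionMatrix,
    low_pct: float = 0.05,
    high_pct: float = 0.95,
    pool_threshold: int = POOL_THRESHOLD_ADULT,
) -> tuple[pd.Index, pd.Index, FilterDiagnostics]:
    """Remove damaged cells and split survivors into expression pools.

    Two criteria are applied: the number of detected genes (cells in the
    low tail, past ``low_pct``, fail) and the mitochondrial transcript
    fraction (cells in the high tail, past ``high_pct``, fail).  Cutoffs
    come from :func:`_rank_size_cutoff`; when no inflection is found the
    percentile itself is used with a warning.

    Returns (high-pool cell ids, low-pool cell ids, diagnostics); the high
    pool holds surviving cells with ``|Ci| > pool_threshold``, the low pool
    the remaining survivors.
    """
    if m.n_cells < 100:
        raise ValueError("cell filtering needs at least 100 cells")
    genes_det = m.genes_detected.astype(float)
    mito = m.mito_fraction

    gene_cut, gene_fb = _rank_size_cutoff(genes_det, low_pct, tail="low")
    mito_cut, mito_fb = _rank_size_cutoff(mito, high_pct, tail="high")
    if gene_fb:
        warnings.warn(
            "no inflection found in the detected-genes rank-size curve; "
            f"falling back to the {low_pct:.0%} percentile", stacklevel=2)
    if mito_fb:
        warnings.warn(
            "no inflection found in the mitochondrial-fraction rank-size curve; "
            f"falling back to the {high_pct:.0%} percentile", stacklevel=2)

    fail_genes = genes_det < gene_cut
    fail_mito = mito > mito_cut
    keep = ~(fail_genes | fail_mito)
    totals = m.cell_totals
    high = m.cell_ids[keep & (totals > pool_threshold)]
    low = m.cell_ids[keep & (totals <= pool_threshold)]
    diag = FilterDiagnostics(
        gene_cutoff=gene_cut, mito_cutoff=mito_cut,
        gene_cutoff_fallback=gene_fb, mito_cutoff_fallback=mito_fb,
        n_removed_genes=int(fail_genes.sum()), n_removed_mito=int(fail_mito.sum()),
    )
    return high, low, diag


def library_normalize(
    m: ExpressionMatrix, log: bool = False, target_sum: float | None = None,
) -> NormalizedMatrix:
    """Scale each cell's counts by ``kappa_bar / |Ci|``; optional log2(1+x).

    After scaling (and before the log) every row sums to ``kappa_bar``.
    ``target_sum`` overrides ``kappa_bar`` — used to put datasets with
    different sequencing depth on one dataset's library-size scale.
    """
    totals = m.cell_totals
    if (totals == 0).any():
        bad = m.cell_ids[totals == 0][:5].tolist()
        raise ValueError(f"cannot normalize zero-count cell(s): {bad}")
    kappa_bar = m.kappa_bar if target_sum is None else float(target_sum)
    scale = kappa_bar / totals
    values = sp.csr_matrix(m.counts.multiply(scale[:, None]))
    if log:
        values = values.copy()
        values.data = np.log2(1.0 + values.data)
    return NormalizedMatrix(values, m.cell_ids, m.gene_ids, kappa_bar, log)


def _dense_columns(x) -> np.ndarray:
    if sp.issparse(x):
        return np.asarray(x.todense(), float)
    return np.asarray(x, float)


def select_genes(
    data,
    method: str,
    alpha: float = 0.8,
    n_top: int = 1000,
    mnr_threshold: float = 4.0,
    dnr_threshold: float = 0.5,
    exclude: pd.Index | None = None,
) -> GeneSelection:
    """Score and select genes by one of three range/dispersion statistics.

    ``data`` is an :class:`ExpressionMatrix` (cells x genes) for ``cov`` and
    ``mnr``, or a gene x sample DataFrame (bulk / pseudo-bulk) for ``dnr``.
    Sigma in the CoV is the population standard deviation.  ``exclude``
    removes genes (e.g. mitochondrial/ribosomal) from the selection but
    their scores are still reported.
    """
    if method in ("cov", "mnr"):
        if not isinstance(data, ExpressionMatrix):
            raise TypeError(f"{method} selection expects an ExpressionMatrix")
        x = _dense_columns(data.counts)
        mu = x.mean(axis=0)
        if method == "cov":
            sigma = x.std(axis=0)  # population SD
            scores = np.log2(1.0 + sigma) - alpha * np.log2(1.0 + mu)
        else:
            rng_ = x.max(axis=0) - x.min(axis=0)
            scores = np.log2(1.0 + rng_) - alpha * np.log2(1.0 + mu)
        index = data.gene_ids
    elif method == "dnr":
        if not isinstance(data, pd.DataFrame):
            raise TypeError("dnr selection expects a gene x sample DataFrame")
        x = data.to_numpy(float)
        scores = (
            np.log2(1.0 + x.max(axis=1))
            - np.log2(1.0 + x.min(axis=1))
            - 0.25 * np.log2(1.0 + np.median(x, axis=1))
        )
        index = data.index
    else:
        raise ValueError(f"unknown gene-selection method {method!r}")

    scores = pd.Series(scores, index=index, name=f"{method}_score")
    eligible = scores.copy()
    if exclude is not None:
        eligible = eligible.drop(pd.Index(exclude).intersection(eligible.index))
    if method == "cov":
        selected = eligible.nlargest(min(n_top, len(eligible))).index
        params = {"alpha": alpha, "n_top": n_top}
    elif method == "mnr":
        selected = eligible.index[eligible > mnr_threshold]
        params = {"alpha": alpha, "threshold": mnr_threshold}
    else:
        selected = eligible.index[eligible > dnr_threshold]
        params = {"threshold": dnr_threshold}
    if len(selected) == 0:
        warnings.warn(f"{method} selection is empty", stacklevel=2)
    return GeneSelection(method, scores, pd.Index(selected), params)


def compute_pca(nm: NormalizedMatrix, genes=None, n_components: int = 100) -> PCAScores:
    """Mean-centered PCA of the (log-normalized) expression of selected genes.

    Component signs are fixed so the largest-magnitude loading of each
    component is positive; requesting more components than the data's rank
    supports truncates with a warning.
    """
    if genes is not None:
        nm = nm.restrict_genes(genes)
    x = nm.dense()
    max_comp = min(x.shape)
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} exceeds min(n_cells, n_genes)="
            f"{max_comp}; truncating", stacklevel=2)
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    load = pca.components_.T  # genes x components
    flip = np.sign(load[np.abs(load).argmax(axis=0), np.arange(load.shape[1])])
    flip[flip == 0] = 1.0
    scores = scores * flip
    load = load * flip
    return PCAScores(
        scores=pd.DataFrame(
            scores, index=nm.cell_ids,
            columns=[f"PC{i+1}" for i in range(scores.shape[1])],
        ),
        loadings=pd.DataFrame(
            load, index=nm.gene_ids,
            columns=[f"PC{i+1}" for i in range(load.shape[1])],
        ),
        explained_variance_ratio=pca.explained_variance_ratio_,
        mean_=pca.mean_,
    )
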