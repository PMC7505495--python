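"""Multiplet (doublet) flagging from cell-class marker co-expression.

A droplet capturing two cells of different classes carries markers of both.
Each cell class has a small marker-gene set; a cell's score for a set is
the raw sum of its transcript counts over the set's genes.  Cells scoring
above threshold for two or more sets are flagged, and — because marker
dropout causes false negatives — whole clusters are flagged when their
flagged fraction exceeds a cutoff (0.30 for adult retina, 0.15 for
organoids).  Score thresholds separating the expressing from the
non-expressing mode are estimated per set from the minimum-density valley
of a 1D kernel density estimate of log2(1 + score).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde
from sklearn.base import BaseEstimator

from .matrix import ExpressionMatrix

__all__ = [
    "MarkerSet",
    "PACKAGED_MARKER_SETS",
    "load_marker_sets",
    "marker_scores",
    "estimate_thresholds",
    "flag_multiplets",
    "MarkerMultipletFlagger",
]


@dataclass
class MarkerSet:
    name: str
    genes: list[str]
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"marker set {self.name!r} has no genes")


def load_marker_sets(path=None) -> dict[str, list[str]]:
    """Load marker sets from a two-column TSV (set name, gene)."""
    if path is None:
        path = resources.files("scretina").joinpath("data/marker_sets.tsv")
    df = pd.read_csv(path, sep="\t", header=None, names=["set", "gene"])
    return {name: list(sub["gene"]) for name, sub in df.groupby("set", sort=False)}


PACKAGED_MARKER_SETS: dict[str, list[str]] = load_marker_sets()


def marker_scores(
    m: ExpressionMatrix, sets: dict[str, list[str]] | list[MarkerSet] | None = None,
    *, normalized: bool = False,
) -> pd.DataFrame:
    """Per-cell raw-count sums over each marker set (cells x sets).

    ``normalized=True`` rescales counts to the dataset-average library size
    before summing — a sensitivity-analysis mode; the default uses raw counts.
    """
    if sets is None:
        sets = PACKAGED_MARKER_SETS
    if isinstance(sets, list):
        sets = {s.name: s.genes for s in sets}
    counts = m.counts
    if normalized:
        scale = m.kappa_bar / np.maximum(m.cell_totals, 1.0)
        counts = counts.multiply(scale[:, None]).tocsr()
    cols = {}
    for name, genes in sets.items():
        present = m.gene_ids.get_indexer(genes)
        present = present[present >= 0]
        if len(present) == 0:
            raise ValueError(f"no genes of marker set {name!r} present in the matrix")
        cols[name] = np.asarray(counts[:, present].sum(axis=1)).ravel()
    return pd.DataFrame(cols, index=m.cell_ids)


def _valley_threshold(scores: np.ndarray) -> tuple[float, bool]:
    """Threshold at the minimum-density point between the two main modes
    of a KDE of log2(1+score); returns (threshold, bimodal?)."""
    x = np.log2(1.0 + scores.astype(float))
    if np.ptp(x) < 1e-12:
        return float(np.quantile(scores, 0.99)), False
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), 512)
    dens = kde(grid)
    interior = np.flatnonzero(
        (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    ) + 1
    peaks = sorted(interior, key=lambda i: -dens[i])
    # include the boundary bins as candidate modes (zero-inflated scores
    # put one mode exactly at the grid edge)
    for edge in (0, len(grid) - 1):
        if all(abs(edge - p) > 2 for p in peaks):
            if (edge == 0 and dens[0] > dens[1]) or (
                edge == len(grid) - 1 and dens[-1] > dens[-2]
            ):
                peaks.append(edge)
    peaks = sorted(peaks, key=lambda i: -dens[i])[:2]
    if len(peaks) < 2:
        return float(np.quantile(scores, 0.99)), False
    lo, hi = sorted(peaks)
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    thr_log = max(grid[valley], grid[lo])  # never below the lower mode
    return float(2.0 ** thr_log - 1.0), True


def estimate_thresholds(
    scores: pd.DataFrame, overrides: dict[str, float] | None = None,
) -> pd.Series:
    """Per-set score thresholds (KDE-valley rule; manual overrides win).

    Unimodal score distributions fall back to the 99th percentile with a
    warning.
    """
    if len(scores) < 100:
        raise ValueError("threshold estimation needs at least 100 cells")
    overrides = overrides or {}
    out = {}
    for name in scores.columns:
        if name in overrides:
            out[name] = float(overrides[name])
            continue
        thr, bimodal = _valley_threshold(scores[name].to_numpy())
        if not bimodal:
            warnings.warn(
                f"marker set {name!r}: score distribution not bimodal; "
                f"threshold set to the 99th percentile ({thr:.3g})",
                stacklevel=2,
            )
        out[name] = thr
    return pd.Series(out, name="threshold")


def flag_multiplets(
    scores: pd.DataFrame,
    thresholds: pd.Series,
    clustering: pd.Series | None = None,
    cluster_fraction: float = 0.30,
) -> pd.DataFrame:
    """Two-stage multiplet flags.

    Stage 1 flags cells strictly above threshold in >= 2 marker sets.
    Stage 2 (when a clustering is given) flags every member of any cluster
    whose flagged fraction strictly exceeds ``cluster_fraction``.
    Returns a frame with boolean ``flagged`` and string ``reason``
    ("two-set", "cluster-fraction", or "").
    """
    above = scores.gt(thresholds, axis=1)
    two_set = above.sum(axis=1) >= 2
    reason = np.where(two_set, "two-set", "")
    flagged = two_set.to_numpy().copy()
    if clustering is not None:
        clustering = clustering.reindex(scores.index)
        for label, members in scores.index.groupby(clustering).items():
            pos = scores.index.get_indexer(members)
            if flagged[pos].mean() > cluster_fraction:
                newly = pos[~flagged[pos]]
                flagged[pos] = True
                reason = reason.astype(object)
                reason[newly] = "cluster-fraction"
    return pd.DataFrame({"flagged": flagged, "reason": reason}, index=scores.index)


class MarkerMultipletFlagger(BaseEstimator):
    """Estimator wrapper: fit() learns per-set thresholds, predict() flags.

    Parameters
    ----------
    sets : mapping of set name -> marker genes (default: packaged retina sets)
    cluster_fraction : flagged-fraction cutoff for stage 2
    threshold_overrides : per-set manual thresholds
    normalized : score on library-normalized rather than raw counts
    """

    def __init__(self, sets=None, cluster_fraction: float = 0.30,
                 threshold_overrides=None, normalized: bool = False):
        self.sets = sets
        self.cluster_fraction = cluster_fraction
        self.threshold_overrides = threshold_overrides
        self.normalized = normalized

    def fit(self, m: ExpressionMatrix, y=None):
        sets = self.sets
        if sets is None:
            # default sets: keep only classes whose markers are in the matrix
            present = set(m.gene_ids)
            sets = {name: genes for name, genes in PACKAGED_MARKER_SETS.items()
                    if any(g in present for g in genes)}
        self.sets_ = sets
        scores = marker_scores(m, sets, normalized=self.normalized)
        self.scores_ = scores
        self.thresholds_ = estimate_thresholds(scores, self.threshold_overrides)
        return self

    def predict(self, m: ExpressionMatrix, clustering: pd.Series | None = None) -> pd.DataFrame:
        if not hasattr(self, "thresholds_"):
            raise RuntimeError("fit() must be called before predict()")
        scores = marker_scores(m, self.sets_, normalized=self.normalized)
        return flag_multiplets(
            scores, self.thresholds_, clustering, self.cluster_fraction
        )
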