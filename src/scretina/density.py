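"""Kernel-density machinery over a 2D embedding of cell transcriptomes.

Cells live in a 2D map (an external embedding or a simulated stand-in).
A Gaussian kernel density estimate of the full map is evaluated on a fixed
341 x 341 grid spanning [-17, +17] at step 0.1, with the bandwidth set
once by Scott's rule and then held constant for every subset or
transcript-weighted density, so that densities of different cell subsets
are directly comparable.

Derived views:

* relative cell density  D = S_subset / (S_full + eps), eps = 0.01;
* gene transcript density: the KDE weighted by per-cell transcript counts
  of one gene, again divided by (S_full + eps);
* probability mass Q = S / ||S||_1, compared across ages by the
  Jensen-Shannon divergence in base 2 (0 for identical distributions,
  1 for disjoint supports) — the transcriptome-stabilization metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .matrix import ExpressionMatrix

__all__ = [
    "DensityGrid",
    "EmbeddingDensity",
    "fit_density",
    "js_divergence",
]

GRID_RANGE = 17.0
GRID_STEP = 0.1
ISODENSITY_LEVEL = 2e-4   # plotting convention only


@dataclass
class DensityGrid:
    """Density values on a fixed rectangular grid (rows = y, cols = x)."""

    values: np.ndarray
    x: np.ndarray
    y: np.ndarray
    bandwidth: tuple[float, float]
    kind: str = "density"   # {density, relative, gene, probability}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.shape != (len(self.y), len(self.x)):
            raise ValueError("grid values shape does not match axes")
        if (self.values < 0).any():
            raise ValueError("density values must be nonnegative")

    def to_probability(self) -> "DensityGrid":
        """L1-normalize the grid into a probability mass function Q."""
        total = self.values.sum()
        if total <= 0:
            raise ValueError("cannot normalize an all-zero grid")
        return DensityGrid(self.values / total, self.x, self.y, self.bandwidth,
                           kind="probability")

    def argmax_xy(self) -> tuple[float, float]:
        iy, ix = np.unravel_index(np.argmax(self.values), self.values.shape)
        return float(self.x[ix]), float(self.y[iy])


def _grid_axes(grid_range: float, step: float) -> np.ndarray:
    n = int(round(2 * grid_range / step)) + 1
    return np.linspace(-grid_range, grid_range, n)


def _as_xy(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        points = points[["x", "y"]].to_numpy()
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("embedding points must be n x 2")
    if not np.isfinite(points).all():
        raise ValueError("embedding coordinates must be finite")
    return points


class EmbeddingDensity(BaseEstimator):
    """Gaussian KDE of a 2D embedding on a fixed evaluation grid.

    ``fit`` estimates the per-axis bandwidth by Scott's rule
    (n^(-1/6) * axis SD) on the full point set and evaluates the full
    density; subsequent subset/gene densities reuse that bandwidth.

    Parameters
    ----------
    grid_range : half-width of the square evaluation window
    grid_step : grid spacing (default 0.1 -> 341 x 341 at range 17)
    eps : additive constant in relative densities, suppressing noise where
        the full density is low
    """

    def __init__(self, grid_range: float = GRID_RANGE, grid_step: float = GRID_STEP,
                 eps: float = 0.01):
        self.grid_range = grid_range
        self.grid_step = grid_step
        self.eps = eps

    # -- core ---------------------------------------------------------
    def fit(self, points, y=None):
        xy = _as_xy(points)
        if len(np.unique(xy, axis=0)) < 2:
            raise ValueError("density estimation needs >= 2 distinct points")
        if np.abs(xy).max() > self.grid_range:
            raise ValueError(
                "embedding coordinates fall outside the evaluation grid; "
                "pass a larger grid_range")
        sx, sy = xy.std(axis=0, ddof=1)
        if sx == 0 or sy == 0:
            raise ValueError("zero bandwidth: points are collinear with an axis")
        factor = len(xy) ** (-1.0 / 6.0)  # Scott's rule, d = 2
        self.bandwidth_ = (factor * sx, factor * sy)
        self.points_ = xy
        if isinstance(points, pd.DataFrame):
            self.index_ = points.index
        else:
            self.index_ = pd.RangeIndex(len(xy))
        axes = _grid_axes(self.grid_range, self.grid_step)
        self.axes_ = axes
        self.grid_ = self._evaluate(xy, None)
        return self

    def _evaluate(self, xy: np.ndarray, weights) -> DensityGrid:
        """Separable Gaussian product-kernel evaluation on the grid."""
        hx, hy = self.bandwidth_
        axes = self.axes_
        if weights is None:
            weights = np.ones(len(xy))
        weights = np.asarray(weights, float)
        w = weights / weights.sum()
        ax = np.exp(-0.5 * ((axes[:, None] - xy[None, :, 0]) / hx) ** 2)
        ay = np.exp(-0.5 * ((axes[:, None] - xy[None, :, 1]) / hy) ** 2)
        vals = (ay * w[None, :]) @ ax.T
        vals /= 2.0 * np.pi * hx * hy
        return DensityGrid(vals, axes, axes, (hx, hy))

    def _require_fit(self):
        if not hasattr(self, "grid_"):
            raise RuntimeError("fit() must be called first")

    # -- derived views --------------------------------------------------
    def subset_density(self, subset) -> DensityGrid:
        """KDE of a subset of the fitted cells, bandwidth held constant.

        ``subset`` is a boolean mask, integer positions, or index labels of
        the fitted point set.
        """
        self._require_fit()
        pos = self._positions(subset)
        if len(pos) < 2:
            raise ValueError("subset density needs >= 2 cells")
        return self._evaluate(self.points_[pos], None)

    def subset_relative_density(self, subset) -> DensityGrid:
        """D = S_subset / (S_full + eps)."""
        sub = self.subset_density(subset)
        rel = sub.values / (self.grid_.values + self.eps)
        return DensityGrid(rel, sub.x, sub.y, sub.bandwidth, kind="relative")

    def gene_density(self, m: ExpressionMatrix, gene: str) -> DensityGrid:
        """Transcript-weighted KDE for one gene (weights = counts per cell)."""
        self._require_fit()
        j = m.gene_ids.get_loc(gene)
        pos = m.cell_ids.get_indexer(self.index_)
        if (pos < 0).any():
            raise KeyError("fitted cells missing from the expression matrix")
        w = np.asarray(m.counts[:, j].todense()).ravel()[pos]
        if w.sum() == 0:
            raise ValueError(f"gene {gene!r} has no transcripts in the fitted cells")
        return self._evaluate(self.points_, w)

    def gene_relative_density(self, m: ExpressionMatrix, gene: str) -> DensityGrid:
        g = self.gene_density(m, gene)
        rel = g.values / (self.grid_.values + self.eps)
        return DensityGrid(rel, g.x, g.y, g.bandwidth, kind="gene")

    def _positions(self, subset) -> np.ndarray:
        subset = np.asarray(subset)
        if subset.dtype == bool:
            if len(subset) != len(self.points_):
                raise ValueError("boolean subset mask has wrong length")
            return np.flatnonzero(subset)
        if subset.dtype.kind in "iu":
            return subset
        pos = self.index_.get_indexer(subset)
        if (pos < 0).any():
            raise KeyError("subset contains cells not in the fitted embedding")
        return pos


def fit_density(points, **kwargs) -> DensityGrid:
    """One-shot full-map density (see :class:`EmbeddingDensity`)."""
    return EmbeddingDensity(**kwargs).fit(points).grid_


def js_divergence(a: DensityGrid, b: DensityGrid) -> float:
    """Jensen-Shannon divergence (base 2) between two density grids.

    Grids are first L1-normalized to probability mass functions; cells
    where both masses vanish contribute nothing.  Symmetric and bounded in
    [0, 1]; 0 for identical grids, 1 for disjoint supports.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("grids have different shapes")
    p = a.to_probability().values.ravel()
    q = b.to_probability().values.ravel()
    m = 0.5 * (p + q)

    def kl(u, v):
        mask = u > 0
        return float(np.sum(u[mask] * np.log2(u[mask] / v[mask])))

    d = 0.5 * kl(p, m) + 0.5 * kl(q, m)
    return float(min(max(d, 0.0), 1.0))
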