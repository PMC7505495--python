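"""Developmental-age prediction from correlation features.

A query transcriptome (bulk sample or single-cell pseudo-bulk) is placed on
the developmental axis of a bulk reference series (e.g. developing human
retina) by regression: the feature vector of a sample is its Spearman rank
correlation to every reference sample over a shared set of
developmentally modulated genes (selected by the median-normalized range,
``dnr`` > 0.5, on each side, intersected), and reference age in weeks is
fit on the reference's self-correlation matrix by ordinary least squares.
Because features outnumber samples the minimum-norm least-squares solution
is used.  Leave-one-out cross-validation predicts each reference sample
from a model trained without its row (its feature column is kept by
default; dropping it too is a switch).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, RegressorMixin

from .matrix import ExpressionMatrix
from .preprocess import select_genes
from .simulate import BulkSeries

__all__ = [
    "build_pseudobulk",
    "correlation_features",
    "shared_dnr_genes",
    "AgeRegressor",
    "train_age_model",
]


def build_pseudobulk(m: ExpressionMatrix, subset=None) -> pd.Series:
    """Per-gene summed raw counts over a subset of cells (default: all)."""
    if subset is None:
        sub = m
    else:
        sub = m.subset_cells(subset)
        if sub.n_cells == 0:
            raise ValueError("pseudo-bulk subset is empty")
    return pd.Series(sub.gene_totals, index=m.gene_ids, name="pseudobulk")


def average_replicates(bulk: BulkSeries) -> BulkSeries:
    """Average samples sharing an age (replicates) into one column."""
    groups = bulk.ages.groupby(bulk.ages).groups
    cols, ages = {}, {}
    for age, samples in groups.items():
        name = samples[0] if len(samples) == 1 else f"age{age:g}"
        cols[name] = bulk.values[samples].mean(axis=1)
        ages[name] = age
    values = pd.DataFrame(cols)
    return BulkSeries(values, pd.Series(ages, name="age_weeks"))


def shared_dnr_genes(a: pd.DataFrame, b: pd.DataFrame,
                     threshold: float = 0.5) -> pd.Index:
    """Intersection of dnr-selected gene sets of two gene x sample tables."""
    sel_a = select_genes(a, "dnr", dnr_threshold=threshold).selected
    sel_b = select_genes(b, "dnr", dnr_threshold=threshold).selected
    return sel_a.intersection(sel_b)


def correlation_features(query, reference: BulkSeries, genes) -> pd.Series:
    """Spearman correlation of a query to each reference sample.

    Computed on log2(1+x)-scaled values over the shared genes; a
    zero-variance side yields a 0 feature with a warning.  Being a rank
    statistic, features are invariant to library-size scaling and any
    monotone transform of the query.
    """
    genes = pd.Index(genes)
    if isinstance(query, pd.Series):
        q = query.reindex(genes)
    else:
        q = pd.Series(np.asarray(query, float), index=genes)
    if q.isna().any():
        raise ValueError("query is missing some shared genes")
    ql = np.log2(1.0 + q.to_numpy(float))
    ref = np.log2(1.0 + reference.values.loc[genes].to_numpy(float))
    feats = {}
    for k, sample in enumerate(reference.values.columns):
        col = ref[:, k]
        if np.ptp(ql) == 0 or np.ptp(col) == 0:
            warnings.warn(
                f"zero-variance vector in correlation with {sample!r}; "
                "feature recorded as 0", stacklevel=2)
            feats[sample] = 0.0
        else:
            feats[sample] = float(spearmanr(ql, col).statistic)
    return pd.Series(feats, name="rs")


class AgeRegressor(BaseEstimator, RegressorMixin):
    """OLS age model on Spearman-correlation features of a bulk reference.

    Parameters
    ----------
    genes : gene ids used for correlations; default: dnr-selected genes of
        the reference itself (intersect with a query-side selection via
        :func:`shared_dnr_genes` for the two-dataset workflow)
    average_replicates : average same-age reference samples first
    loo_drop_column : in leave-one-out, also drop the held-out sample's
        feature column (default keeps it)

    Attributes
    ----------
    features_ : reference self-correlation matrix (samples x samples)
    coef_, intercept_ : regression weights
    loo_predictions_ : per-reference-sample held-out age predictions
    """

    def __init__(self, genes=None, average_replicates: bool = False,
                 loo_drop_column: bool = False, dnr_threshold: float = 0.5,
                 ridge_alpha: float = 1e-4):
        self.genes = genes
        self.average_replicates = average_replicates
        self.loo_drop_column = loo_drop_column
        self.dnr_threshold = dnr_threshold
        self.ridge_alpha = ridge_alpha

    def fit(self, reference: BulkSeries, y=None):
        ref = average_replicates(reference) if self.average_replicates else reference
        if ref.values.shape[1] < 3:
            raise ValueError("age model needs >= 3 reference samples")
        if self.genes is None:
            genes = select_genes(ref.values, "dnr",
                                 dnr_threshold=self.dnr_threshold).selected
        else:
            genes = pd.Index(self.genes)
        if len(genes) == 0:
            raise ValueError("empty gene set for the age model")
        self.genes_ = genes
        self.reference_ = ref
        samples = ref.values.columns
        feat = pd.DataFrame(
            {s: correlation_features(ref.values[s], ref, genes) for s in samples}
        ).T  # rows: sample, cols: feature-per-reference-sample
        self.features_ = feat
        ages = ref.ages.to_numpy(float)
        self.ages_ = pd.Series(ages, index=samples, name="age_weeks")
        self.intercept_, self.coef_ = self._solve(feat.to_numpy(), ages)
        self.loo_predictions_ = self._loo(feat, ages)
        return self

    def _solve(self, X: np.ndarray, y: np.ndarray,
               held_out: bool = False) -> tuple[float, np.ndarray]:
        """OLS when the design has full rank.

        Singular designs (features outnumber samples, the usual case here)
        take the minimum-norm least-squares solution, which interpolates
        the training rows exactly; held-out (LOO) refits instead use a
        light ridge penalty, which stabilizes prediction at the removed
        sample.
        """
        A = np.column_stack([np.ones(len(X)), X])
        rank = np.linalg.matrix_rank(A)
        if rank >= A.shape[1]:
            w, *_ = np.linalg.lstsq(A, y, rcond=None)
            return float(w[0]), w[1:]
        if not held_out:
            warnings.warn(
                "singular age-model design; using the minimum-norm "
                "least-squares solution", stacklevel=3)
            w, *_ = np.linalg.lstsq(A, y, rcond=None)
            return float(w[0]), w[1:]
        xm, ym = X.mean(axis=0), y.mean()
        xc = X - xm
        w = np.linalg.solve(
            xc.T @ xc + self.ridge_alpha * np.eye(X.shape[1]), xc.T @ (y - ym))
        return float(ym - xm @ w), w

    def _loo(self, feat: pd.DataFrame, ages: np.ndarray) -> pd.Series:
        preds = {}
        for i, sample in enumerate(feat.index):
            rows = np.delete(np.arange(len(feat)), i)
            cols = rows if self.loo_drop_column else np.arange(feat.shape[1])
            X = feat.to_numpy()[np.ix_(rows, cols)]
            b0, b = self._solve(X, ages[rows], held_out=True)
            preds[sample] = float(b0 + feat.to_numpy()[i, cols] @ b)
        return pd.Series(preds, name="loo_predicted_age")

    # ------------------------------------------------------------------
    def features_for(self, query) -> pd.Series:
        """Correlation features of a query expression vector."""
        self._check_fitted()
        return correlation_features(query, self.reference_, self.genes_)

    def predict(self, queries) -> pd.DataFrame:
        """Predict ages for query expression vectors.

        ``queries``: gene x sample DataFrame (or a single Series).  Returns
        a frame with ``predicted_age`` and an ``extrapolated`` flag set
        when the prediction leaves the reference age range.
        """
        self._check_fitted()
        if isinstance(queries, pd.Series):
            queries = queries.to_frame()
        rows = {}
        for s in queries.columns:
            f = self.features_for(queries[s])
            rows[s] = self.predict_from_features(f.to_numpy())
        pred = pd.Series(rows, name="predicted_age")
        lo, hi = self.ages_.min(), self.ages_.max()
        return pd.DataFrame(
            {"predicted_age": pred, "extrapolated": (pred < lo) | (pred > hi)}
        )

    def predict_from_features(self, features) -> float:
        self._check_fitted()
        features = np.asarray(features, float)
        if features.shape != self.coef_.shape:
            raise ValueError(
                f"expected {self.coef_.shape[0]} features, got {features.shape}")
        if np.isnan(features).any():
            raise ValueError("missing (NaN) features")
        return float(self.intercept_ + features @ self.coef_)

    def loo_rmse(self) -> float:
        self._check_fitted()
        err = self.loo_predictions_.to_numpy() - self.ages_.to_numpy()
        return float(np.sqrt(np.mean(err**2)))

    def loo_r2(self) -> float:
        self._check_fitted()
        y = self.ages_.to_numpy()
        err = self.loo_predictions_.to_numpy() - y
        return float(1.0 - np.sum(err**2) / np.sum((y - y.mean()) ** 2))

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("fit() must be called first")

    def to_json_dict(self) -> dict:
        self._check_fitted()
        return {
            "samples": list(map(str, self.ages_.index)),
            "ages": self.ages_.tolist(),
            "genes": list(map(str, self.genes_)),
            "intercept": self.intercept_,
            "coef": self.coef_.tolist(),
            "loo_predictions": self.loo_predictions_.tolist(),
        }


def train_age_model(reference: BulkSeries, genes=None, **kwargs) -> AgeRegressor:
    """Functional wrapper over :class:`AgeRegressor`."""
    return AgeRegressor(genes=genes, **kwargs).fit(reference)
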