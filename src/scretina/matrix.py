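"""Count-matrix containers and standard-format I/O.

The central object is :class:`ExpressionMatrix`: a sparse cell x gene table
of unique-transcript (UMI) counts together with cell/gene identifiers and
gene annotations (mitochondrial / ribosomal-protein flags).  Derived
quantities follow the usual contingency-table bookkeeping: per-cell totals
``|Ci|``, per-gene totals ``|Gj|`` and the grand total ``kappa``, with
``kappa_bar = kappa / n_cells`` the dataset-average library size used for
library normalization.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "ExpressionMatrix",
    "NormalizedMatrix",
    "read_counts",
    "write_counts_mtx",
    "read_dense_tsv",
    "write_dense_tsv",
]

_MITO_RE = re.compile(r"^MT-", re.IGNORECASE)
_RIBO_RE = re.compile(r"^RP[SL]\d", re.IGNORECASE)


def _as_unique_index(ids, what: str) -> pd.Index:
    idx = pd.Index(np.asarray(ids, dtype=object), dtype=object)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate {what} ids: {dups}")
    return idx


@dataclass
class ExpressionMatrix:
    """Sparse cell x gene unique-transcript count matrix.

    Parameters
    ----------
    counts
        Nonnegative integer counts, cells as rows, genes as columns.
        Stored as CSR.
    cell_ids, gene_ids
        Unique string identifiers for rows / columns.
    mito_mask, ribo_mask
        Boolean per-gene flags.  If omitted they are inferred from gene
        names ("MT-" prefix; "RPS"/"RPL" prefix).
    """

    counts: sp.csr_matrix
    cell_ids: pd.Index
    gene_ids: pd.Index
    mito_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    ribo_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be nonnegative")
        self.cell_ids = _as_unique_index(self.cell_ids, "cell")
        self.gene_ids = _as_unique_index(self.gene_ids, "gene")
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )
        if self.mito_mask is None:
            self.mito_mask = np.fromiter(
                (bool(_MITO_RE.match(g)) for g in self.gene_ids), bool, len(self.gene_ids)
            )
        else:
            self.mito_mask = np.asarray(self.mito_mask, bool)
        if self.ribo_mask is None:
            self.ribo_mask = np.fromiter(
                (bool(_RIBO_RE.match(g)) for g in self.gene_ids), bool, len(self.gene_ids)
            )
        else:
            self.ribo_mask = np.asarray(self.ribo_mask, bool)

    # -- contingency-table totals ------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_totals(self) -> np.ndarray:
        """Per-cell transcript totals ``|Ci|``."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    @property
    def gene_totals(self) -> np.ndarray:
        """Per-gene transcript totals ``|Gj|``."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    @property
    def kappa(self) -> float:
        """Grand total number of unique transcripts."""
        return float(self.counts.sum())

    @property
    def kappa_bar(self) -> float:
        """Average transcripts per cell, ``kappa / n_cells``."""
        return self.kappa / self.n_cells

    @property
    def mito_fraction(self) -> np.ndarray:
        """Per-cell fraction of transcripts from mitochondrial genes."""
        tot = self.cell_totals
        mito = np.asarray(self.counts[:, self.mito_mask].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(tot > 0, mito / np.maximum(tot, 1), 0.0)
        return frac

    @property
    def genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with at least one transcript."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    # -- subsetting ---------------------------------------------------
    def subset_cells(self, cells) -> "ExpressionMatrix":
        """Return a new matrix restricted to the given cells (ids or bool mask)."""
        idx = self._cell_indexer(cells)
        return ExpressionMatrix(
            self.counts[idx], self.cell_ids[idx], self.gene_ids,
            mito_mask=self.mito_mask, ribo_mask=self.ribo_mask,
        )

    def subset_genes(self, genes) -> "ExpressionMatrix":
        idx = self._gene_indexer(genes)
        return ExpressionMatrix(
            self.counts[:, idx], self.cell_ids, self.gene_ids[idx],
            mito_mask=self.mito_mask[idx], ribo_mask=self.ribo_mask[idx],
        )

    def _cell_indexer(self, cells) -> np.ndarray:
        cells = np.asarray(cells)
        if cells.dtype == bool:
            if cells.shape != (self.n_cells,):
                raise ValueError("boolean cell mask has wrong length")
            return np.flatnonzero(cells)
        pos = self.cell_ids.get_indexer(cells)
        if (pos < 0).any():
            raise KeyError(f"unknown cell ids: {np.asarray(cells)[pos < 0][:5].tolist()}")
        return pos

    def _gene_indexer(self, genes) -> np.ndarray:
        genes = np.asarray(genes)
        if genes.dtype == bool:
            if genes.shape != (self.n_genes,):
                raise ValueError("boolean gene mask has wrong length")
            return np.flatnonzero(genes)
        pos = self.gene_ids.get_indexer(genes)
        if (pos < 0).any():
            raise KeyError(f"unknown gene ids: {np.asarray(genes)[pos < 0][:5].tolist()}")
        return pos

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def to_anndata(self):
        """Convenience export to an AnnData object (anndata must be installed)."""
        import anndata

        return anndata.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=self.cell_ids.astype(str)),
            var=pd.DataFrame(
                {"mito": self.mito_mask, "ribo": self.ribo_mask},
                index=self.gene_ids.astype(str),
            ),
        )


@dataclass
class NormalizedMatrix:
    """Library-normalized expression, optionally log2(1+x)-transformed.

    When not logged every row sums to ``kappa_bar`` of the source matrix.
    """

    values: sp.csr_matrix
    cell_ids: pd.Index
    gene_ids: pd.Index
    kappa_bar: float
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.cell_ids = pd.Index(self.cell_ids)
        self.gene_ids = pd.Index(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())

    def restrict_genes(self, genes) -> "NormalizedMatrix":
        pos = self.gene_ids.get_indexer(np.asarray(genes))
        if (pos < 0).any():
            raise KeyError("gene(s) not present in normalized matrix")
        return NormalizedMatrix(
            self.values[:, pos], self.cell_ids, self.gene_ids[pos],
            self.kappa_bar, self.log_transformed,
        )


# ---------------------------------------------------------------------
# I/O: 10x-style MTX triplet and dense TSV
# ---------------------------------------------------------------------

def write_counts_mtx(m: ExpressionMatrix, outdir) -> None:
    """Write a 10x-convention MTX triplet (genes are matrix rows)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(m.counts.T), field="integer")
    pd.Series(m.gene_ids).to_csv(outdir / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(m.cell_ids).to_csv(outdir / "barcodes.tsv", sep="\t", header=False, index=False)


def _read_mtx_triplet(path: Path, mito_genes=None) -> ExpressionMatrix:
    mat = scipy.io.mmread(str(path / "matrix.mtx"))
    genes = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    mat = sp.csr_matrix(mat.T)  # stored genes x cells
    if mat.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix.mtx is {mat.T.shape} (genes x cells) but features.tsv has "
            f"{len(genes)} genes and barcodes.tsv {len(cells)} cells"
        )
    mito = None
    if mito_genes is not None:
        mito = genes.isin(set(mito_genes)).to_numpy()
    return ExpressionMatrix(mat, cells, genes, mito_mask=mito)


def read_dense_tsv(path, mito_genes=None) -> ExpressionMatrix:
    """Read a dense cell x gene TSV (first column = cell id, header = gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    mito = None
    if mito_genes is not None:
        mito = df.columns.isin(set(mito_genes)).to_numpy()
    return ExpressionMatrix(
        sp.csr_matrix(df.to_numpy()), df.index.astype(str), df.columns.astype(str),
        mito_mask=mito,
    )


def write_dense_tsv(m: ExpressionMatrix, path) -> None:
    pd.DataFrame(m.dense(), index=m.cell_ids, columns=m.gene_ids).to_csv(path, sep="\t")


def read_counts(path, mito_genes=None) -> ExpressionMatrix:
    """Read counts from an MTX triplet directory or a dense TSV file.

    Mitochondrial genes are flagged by "MT-" prefix unless an explicit
    ``mito_genes`` list is given.
    """
    path = Path(path)
    if path.is_dir():
        return _read_mtx_triplet(path, mito_genes)
    return read_dense_tsv(path, mito_genes)
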