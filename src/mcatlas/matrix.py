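"""Sparse UMI count matrix container (genes x cells)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["UMICountMatrix"]


@dataclass
class UMICountMatrix:
    """Genes x cells matrix of non-negative integer UMI counts.

    Parameters
    ----------
    counts
        Sparse matrix, shape ``(n_genes, n_cells)``; stored as CSC so
        that per-cell column access is cheap.
    gene_ids, cell_ids
        Unique label vectors matching the matrix dimensions.
    """

    counts: sp.spmatrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative entries in UMI count matrix")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene ids are not unique")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("cell ids are not unique")

    # -- basic accessors -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cell_totals(self) -> np.ndarray:
        """Total UMIs per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def gene_totals(self) -> np.ndarray:
        """Total UMIs per gene."""
        return np.asarray(self.counts.sum(axis=1)).ravel()

    # -- subsetting ------------------------------------------------------
    def subset_cells(self, index: np.ndarray) -> "UMICountMatrix":
        """Return a new matrix restricted to cells at integer ``index``."""
        index = np.asarray(index)
        return UMICountMatrix(self.counts[:, index], self.gene_ids, self.cell_ids[index])

    def subset_genes(self, index: np.ndarray) -> "UMICountMatrix":
        index = np.asarray(index)
        return UMICountMatrix(self.counts[index, :], self.gene_ids[index], self.cell_ids)

    def gene_index(self, gene_ids) -> np.ndarray:
        """Integer row index of each requested gene id."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        return np.array([lookup[g] for g in gene_ids], dtype=int)

    def copy(self) -> "UMICountMatrix":
        return UMICountMatrix(self.counts.copy(), self.gene_ids.copy(), self.cell_ids.copy())
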