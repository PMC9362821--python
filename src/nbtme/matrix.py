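"""In-memory expression containers.

Genes are rows and cells are columns throughout the package, mirroring the
on-disk 10x triplet convention (``matrix.mtx`` with genes as rows). Counts
are kept sparse; log-normalized expression is kept as a dense
:class:`pandas.DataFrame` because every downstream statistic (rank sums,
binned-control scores, cluster means) is computed over dense slices anyway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountMatrix", "LogNormMatrix"]


@dataclass
class CountMatrix:
    """Sparse non-negative integer gene x cell matrix for one species.

    Parameters
    ----------
    matrix
        ``(n_genes, n_cells)`` sparse matrix of raw UMI counts.
    genes, cells
        Unique identifiers for rows and columns.
    """

    matrix: sp.spmatrix
    genes: pd.Index
    cells: pd.Index

    def __post_init__(self) -> None:
        self.matrix = sp.csr_matrix(self.matrix)
        self.genes = pd.Index(self.genes)
        self.cells = pd.Index(self.cells)
        if self.matrix.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not self.genes.is_unique:
            raise ValueError("gene identifiers must be unique")
        if not self.cells.is_unique:
            raise ValueError("cell identifiers must be unique")
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(self.matrix.dtype, np.integer):
            data = self.matrix.data
            if data.size and not np.allclose(data, np.round(data)):
                raise ValueError("counts must be integers")
            self.matrix = self.matrix.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def cell_totals(self) -> pd.Series:
        """Total counts per cell (library size)."""
        totals = np.asarray(self.matrix.sum(axis=0)).ravel()
        return pd.Series(totals, index=self.cells, name="total_counts")

    def to_frame(self) -> pd.DataFrame:
        """Dense gene x cell DataFrame (small matrices only)."""
        return pd.DataFrame(
            self.matrix.toarray(), index=self.genes, columns=self.cells
        )

    def subset_cells(self, cells: Sequence[str]) -> "CountMatrix":
        idx = self.cells.get_indexer(pd.Index(cells))
        if (idx < 0).any():
            missing = pd.Index(cells)[idx < 0].tolist()
            raise KeyError(f"unknown cells: {missing[:5]}")
        return CountMatrix(self.matrix[:, idx], self.genes, pd.Index(cells))

    def equals(self, other: "CountMatrix") -> bool:
        return (
            self.genes.equals(other.genes)
            and self.cells.equals(other.cells)
            and (self.matrix != other.matrix).nnz == 0
        )


@dataclass
class LogNormMatrix:
    """Depth-normalized, log1p-transformed expression (gene x cell).

    ``values[g, c] = log(1 + count[g, c] * scale_factor / total(c))`` with
    natural log; produced by :func:`nbtme.preprocess.lognormalize`.
    """

    values: pd.DataFrame
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        if not self.values.index.is_unique or not self.values.columns.is_unique:
            raise ValueError("gene and cell identifiers must be unique")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def cells(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, cells: Sequence[str]) -> "LogNormMatrix":
        return LogNormMatrix(self.values.loc[:, list(cells)], self.scale_factor)

    def subset_genes(self, genes: Sequence[str]) -> "LogNormMatrix":
        return LogNormMatrix(self.values.loc[list(genes)], self.scale_factor)
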