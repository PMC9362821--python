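"""Reading and writing droplet count matrices in the 10x triplet layout.

A directory holds ``matrix.mtx`` (Matrix Market coordinate, genes as rows),
``features.tsv`` (gene id, gene name, feature type) and ``barcodes.tsv``
(one cell barcode per line), all uncompressed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .matrix import CountMatrix

__all__ = ["write_tenx", "read_tenx"]

MATRIX_FILE = "matrix.mtx"
FEATURES_FILE = "features.tsv"
BARCODES_FILE = "barcodes.tsv"


def write_tenx(matrix: CountMatrix, directory) -> Path:
    """Write a :class:`CountMatrix` as an uncompressed 10x triplet directory.

    Round-trips exactly through :func:`read_tenx` (same counts, same gene and
    barcode order).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    coo = sp.coo_matrix(matrix.matrix)
    scipy.io.mmwrite(str(directory / MATRIX_FILE), coo, field="integer")
    features = pd.DataFrame(
        {
            "gene_id": matrix.genes,
            "gene_name": matrix.genes,
            "feature_type": "Gene Expression",
        }
    )
    features.to_csv(directory / FEATURES_FILE, sep="\t", header=False, index=False)
    pd.Series(matrix.cells).to_csv(
        directory / BARCODES_FILE, sep="\t", header=False, index=False
    )
    return directory


def read_tenx(directory) -> CountMatrix:
    """Read a 10x triplet directory written by :func:`write_tenx`."""
    directory = Path(directory)
    mat = sp.csr_matrix(scipy.io.mmread(str(directory / MATRIX_FILE)))
    features = pd.read_csv(
        directory / FEATURES_FILE, sep="\t", header=None, dtype=str
    )
    barcodes = pd.read_csv(
        directory / BARCODES_FILE, sep="\t", header=None, dtype=str
    )
    return CountMatrix(mat, pd.Index(features[0]), pd.Index(barcodes[0]))
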