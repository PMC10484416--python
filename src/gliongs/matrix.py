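"""Expression-matrix container and plain-text readers/writers.

The matrix is stored dense (genes x cells) in a :class:`pandas.DataFrame`;
datasets handled here are desk-scale (thousands of cells), so sparsity is not
worth the indirection. Each matrix carries the sequencing protocol
(full-length TPM vs droplet UMI) because normalization and CNA inference
depend on it, and a layer tag so that operations can assert they received
raw counts/TPM or log-normalized values.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

PROTOCOL_TPM = "TPM-full-length"
PROTOCOL_UMI = "UMI-droplet"

_PROTOCOL_ALIASES = {
    "tpm": PROTOCOL_TPM,
    "smart-seq": PROTOCOL_TPM,
    PROTOCOL_TPM.lower(): PROTOCOL_TPM,
    "umi": PROTOCOL_UMI,
    "10x": PROTOCOL_UMI,
    "drop-seq": PROTOCOL_UMI,
    PROTOCOL_UMI.lower(): PROTOCOL_UMI,
}

LAYER_RAW = "raw"
LAYER_NORMALIZED = "normalized"


def normalize_protocol(protocol: str) -> str:
    try:
        return _PROTOCOL_ALIASES[protocol.lower()]
    except KeyError:
        raise ValueError(
            f"unknown protocol {protocol!r}; expected one of "
            f"{PROTOCOL_TPM!r} (alias 'tpm') or {PROTOCOL_UMI!r} (alias 'umi')"
        ) from None


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x cells expression values with protocol and layer metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are cell ids. Non-negative.
    protocol
        ``"TPM-full-length"`` or ``"UMI-droplet"`` (short aliases accepted).
    layer
        ``"raw"`` (TPM or UMI counts) or ``"normalized"`` (log scale).
    """

    values: pd.DataFrame
    protocol: str
    layer: str = LAYER_RAW

    def __post_init__(self) -> None:
        self.protocol = normalize_protocol(self.protocol)
        if self.layer not in (LAYER_RAW, LAYER_NORMALIZED):
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][:5].tolist()
            raise ValueError(f"duplicate gene ids, e.g. {dup}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][:5].tolist()
            raise ValueError(f"duplicate cell ids, e.g. {dup}")
        arr = self.values.to_numpy()
        if arr.size and float(np.nanmin(arr)) < 0:
            raise ValueError("expression values must be non-negative")

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, layer: str | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(values, self.protocol, layer or self.layer)

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return self.with_values(self.values.loc[genes])

    def subset_cells(self, cells) -> "ExpressionMatrix":
        return self.with_values(self.values[list(cells)])


# -- I/O -----------------------------------------------------------------

def read_dense_tsv(path, protocol: str, layer: str = LAYER_RAW) -> ExpressionMatrix:
    """Read a dense genes-x-cells TSV (first column gene ids, header cell ids)."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values, protocol, layer)


def write_dense_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_mtx_dir(directory, protocol: str, layer: str = LAYER_RAW) -> ExpressionMatrix:
    """Read a 10X-style triplet: matrix.mtx, genes.tsv, barcodes.tsv."""
    directory = Path(directory)
    mat = scipy.io.mmread(directory / "matrix.mtx")
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)[0]
    cells = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0]
    values = pd.DataFrame(
        np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat),
        index=genes.to_numpy(),
        columns=cells.to_numpy(),
    )
    return ExpressionMatrix(values, protocol, layer)


def write_mtx_dir(matrix: ExpressionMatrix, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sparse = scipy.sparse.coo_matrix(matrix.values.to_numpy())
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sparse)
    pd.Series(matrix.gene_ids).to_csv(
        directory / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(matrix.cell_ids).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
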