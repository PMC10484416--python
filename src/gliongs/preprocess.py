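"""Cell/gene filtering and normalization of expression matrices.

Full-length (Smart-seq style) data arrive as TPM and are transformed to
``E = log2(TPM/10 + 1)``; droplet UMI counts are library-size normalized to
``ln(count / cell_total * scale + 1)``. Low-complexity cells are removed by
joint thresholds on detected genes (nFeature) and total signal (nCount), and
mitochondrial genes are dropped before downstream analysis.

The removal clause couples the two thresholds; by default a cell is removed
only when BOTH its detected-gene count and its total signal fall below their
thresholds (``filter_logic="and"``); ``"or"`` removes on either. nCount is
computed before mitochondrial-gene removal.
"""

from __future__ import annotations

import numpy as np

from .matrix import (
    LAYER_NORMALIZED,
    LAYER_RAW,
    PROTOCOL_TPM,
    PROTOCOL_UMI,
    ExpressionMatrix,
)


def log_transform_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """E = log2(TPM/10 + 1), elementwise, for full-length TPM matrices."""
    if matrix.protocol != PROTOCOL_TPM:
        raise ValueError(
            "log_transform_tpm expects TPM-full-length input; "
            "use normalize_umi for UMI-droplet matrices"
        )
    if matrix.layer != LAYER_RAW:
        raise ValueError("matrix already normalized")
    values = np.log2(matrix.values / 10.0 + 1.0)
    return matrix.with_values(values, LAYER_NORMALIZED)


def normalize_umi(matrix: ExpressionMatrix, scale: float = 1e4) -> ExpressionMatrix:
    """Library-size normalization: x -> ln(x / cell_total * scale + 1)."""
    if matrix.protocol != PROTOCOL_UMI:
        raise ValueError("normalize_umi expects UMI-droplet input")
    if matrix.layer != LAYER_RAW:
        raise ValueError("matrix already normalized")
    totals = matrix.values.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"cells with zero total counts: {zero}")
    values = np.log1p(matrix.values / totals * scale)
    return matrix.with_values(values, LAYER_NORMALIZED)


def filter_cells(
    matrix: ExpressionMatrix,
    min_features: int = 3000,
    min_counts: float = 4000,
    filter_logic: str = "and",
) -> tuple[ExpressionMatrix, list[str]]:
    """Remove low-complexity cells; returns (filtered matrix, removed ids).

    A cell's nFeature is its number of genes with value > 0 and its nCount
    the column sum of the raw layer. With ``filter_logic="and"`` (default) a
    cell is removed iff nFeature < min_features AND nCount < min_counts;
    with ``"or"``, iff either falls below its threshold.
    """
    if matrix.layer != LAYER_RAW:
        raise ValueError("filter_cells operates on the raw layer")
    if filter_logic not in ("and", "or"):
        raise ValueError("filter_logic must be 'and' or 'or'")
    n_features = (matrix.values > 0).sum(axis=0)
    n_counts = matrix.values.sum(axis=0)
    low_feat = n_features < min_features
    low_count = n_counts < min_counts
    removed = (low_feat & low_count) if filter_logic == "and" else (low_feat | low_count)
    removed_ids = matrix.cell_ids[removed].tolist()
    if removed.all():
        raise ValueError(
            f"all {matrix.n_cells} cells removed by filter "
            f"(min_features={min_features}, min_counts={min_counts})"
        )
    kept = matrix.with_values(matrix.values.loc[:, ~removed])
    return kept, removed_ids


def remove_mito_genes(matrix: ExpressionMatrix, prefix: str = "MT-") -> ExpressionMatrix:
    """Drop genes whose id starts with the mitochondrial prefix.

    Matching is case-insensitive so both human ``MT-ND1`` and mouse
    ``mt-Nd1`` naming are covered by the default prefix.
    """
    is_mito = matrix.gene_ids.str.lower().str.startswith(prefix.lower())
    if not is_mito.any():
        return matrix
    return matrix.with_values(matrix.values.loc[~is_mito])
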