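"""Copy-number-aberration inference from expression moving averages.

The method smooths per-gene relative expression over a window of 101
neighbouring genes in genomic order, subtracts a baseline profile computed
from reference (normal) cells, and summarizes each cell by its CNA signal
(mean squared relative CNA over all kept genes) and CNA correlation
(Pearson correlation of its profile with the mean profile of non-reference
cells from the same sample). Cells with signal > 0.02 and correlation > 0.4
carry CNA evidence of malignancy.

Windows never cross a chromosome boundary; at chromosome ends the divisor
is the actual window length (it is exactly 101 for interior genes).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .matrix import PROTOCOL_TPM, PROTOCOL_UMI, ExpressionMatrix
from .preprocess import log_transform_tpm

_HUMAN_KARYOTYPE = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
_MOUSE_KARYOTYPE = [f"chr{i}" for i in range(1, 20)] + ["chrX", "chrY"]


@dataclasses.dataclass
class CNAProfile:
    relative_cna: pd.DataFrame   # genes x cells, baseline-subtracted
    signal: pd.Series            # per cell, mean squared relative CNA
    correlation: pd.Series       # per cell, Pearson vs sample mean profile
    baseline: pd.Series          # per kept gene
    reference_cells: list


def _karyotype_rank(chroms: pd.Series) -> np.ndarray:
    order = {c: i for i, c in enumerate(_HUMAN_KARYOTYPE)}
    extra = sorted(set(chroms) - set(order))
    for c in extra:
        order[c] = len(order) + extra.index(c)
    return chroms.map(order).to_numpy()


def order_genes(gene_annotation: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Genes sorted by karyotype chromosome order then start (ties: gene id).

    ``gene_annotation`` needs columns gene, chrom, start. Genes without
    coordinates (NaN) are excluded with a warning.
    """
    ann = gene_annotation.copy()
    if genes is not None:
        known = ann[ann["gene"].isin(genes)]
        missing = len(set(genes)) - len(known)
        if missing:
            warnings.warn(f"{missing} genes lack coordinates and are excluded from CNA")
        ann = known
    bad = ann["chrom"].isna() | ann["start"].isna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} genes lack coordinates and are excluded from CNA")
        ann = ann[~bad]
    rank = _karyotype_rank(ann["chrom"])
    order = np.lexsort((ann["gene"].to_numpy(), ann["start"].to_numpy(), rank))
    return ann.iloc[order].reset_index(drop=True)


def aggregate_filter(matrix: ExpressionMatrix, threshold: float = 4.0) -> list[str]:
    """Genes with aggregate expression Ea = log2(mean TPM + 1) strictly > 4.

    For droplet data, counts-per-10k stand in for TPM on the same scale.
    """
    values = matrix.values
    if matrix.protocol == PROTOCOL_UMI:
        totals = values.sum(axis=0)
        totals[totals == 0] = 1.0
        values = values / totals * 1e4
    ea = np.log2(values.mean(axis=1) + 1.0)
    return ea.index[ea > threshold].tolist()


def relative_expression(matrix: ExpressionMatrix, kept_genes: list[str]) -> pd.DataFrame:
    """Per-gene centered log expression Er_ij = E_ij - mean_j(E_ij)."""
    if matrix.protocol == PROTOCOL_TPM and matrix.layer == "raw":
        e_layer = log_transform_tpm(matrix).values
    else:
        e_layer = matrix.values
    sub = e_layer.loc[kept_genes]
    return sub.sub(sub.mean(axis=1), axis=0)


def moving_average_cna(
    er: pd.DataFrame,
    ordered_annotation: pd.DataFrame,
    half_window: int = 50,
) -> pd.DataFrame:
    """Windowed mean of Er over up to ``2*half_window+1`` genes per chromosome.

    Genes are processed in the order given by ``ordered_annotation``
    (restricted to genes present in ``er``); the window is truncated at
    chromosome ends with the divisor equal to the actual window size.
    """
    ann = ordered_annotation[ordered_annotation["gene"].isin(er.index)]
    out_blocks = []
    for chrom, block in ann.groupby("chrom", sort=False):
        genes = block["gene"].tolist()
        x = er.loc[genes].to_numpy()
        n = len(genes)
        if n < 2:
            warnings.warn(
                f"{chrom} has {n} kept gene(s); passed through unsmoothed"
            )
            out_blocks.append(pd.DataFrame(x, index=genes, columns=er.columns))
            continue
        csum = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
        lo = np.maximum(np.arange(n) - half_window, 0)
        hi = np.minimum(np.arange(n) + half_window, n - 1)
        sums = csum[hi + 1] - csum[lo]
        sizes = (hi - lo + 1).astype(float)
        out_blocks.append(
            pd.DataFrame(sums / sizes[:, None], index=genes, columns=er.columns)
        )
    return pd.concat(out_blocks)


def cna_stats(
    cna: pd.DataFrame,
    reference_cells: list[str],
    sample_of_cell: pd.Series | None = None,
    leave_one_out: bool = True,
) -> CNAProfile:
    """Baseline-subtract the CNA matrix and summarize each cell.

    ``reference_cells`` are the normal cells whose mean CNA defines the
    per-gene baseline. The CNA correlation of cell j is the Pearson
    correlation between its relative profile and the mean relative profile
    of non-reference cells from the same sample (excluding j itself when
    ``leave_one_out``). Datasets without reference cells cannot be scored
    (the CNA criterion is then not applicable).
    """
    reference_cells = [c for c in reference_cells if c in cna.columns]
    if not reference_cells:
        raise ValueError(
            "no reference (normal) cells available: skip the CNA criterion "
            "for this dataset"
        )
    if sample_of_cell is None:
        sample_of_cell = pd.Series("sample0", index=cna.columns)
    sample_of_cell = sample_of_cell.reindex(cna.columns)

    baseline = cna[reference_cells].mean(axis=1)
    rel = cna.sub(baseline, axis=0)
    signal = (rel**2).mean(axis=0)

    is_ref = cna.columns.isin(reference_cells)
    corr = pd.Series(np.nan, index=cna.columns)
    rel_np = rel.to_numpy()
    for sample in sample_of_cell.dropna().unique():
        in_sample = (sample_of_cell == sample).to_numpy()
        nonref = in_sample & ~is_ref
        n_nonref = int(nonref.sum())
        if n_nonref == 0:
            warnings.warn(f"sample {sample!r} has no non-reference cells")
            continue
        total = rel_np[:, nonref].sum(axis=1)
        for j in np.flatnonzero(in_sample):
            if leave_one_out and nonref[j]:
                if n_nonref == 1:
                    continue  # profile undefined; correlation stays NaN
                mean_profile = (total - rel_np[:, j]) / (n_nonref - 1)
            else:
                mean_profile = total / n_nonref
            v = rel_np[:, j]
            if v.std() == 0 or mean_profile.std() == 0:
                continue
            corr.iloc[j] = float(np.corrcoef(v, mean_profile)[0, 1])
    return CNAProfile(
        relative_cna=rel,
        signal=signal.rename("cna_signal"),
        correlation=corr.rename("cna_correlation"),
        baseline=baseline.rename("baseline"),
        reference_cells=list(reference_cells),
    )


def cna_malignant_flag(
    profile: CNAProfile,
    signal_cut: float = 0.02,
    corr_cut: float = 0.4,
) -> pd.Series:
    """Strict conjunction: CNA signal > 0.02 AND CNA correlation > 0.4."""
    flag = (profile.signal > signal_cut) & (profile.correlation > corr_cut)
    return flag.fillna(False).rename("cna_malignant")


def run_cna(
    matrix: ExpressionMatrix,
    gene_annotation: pd.DataFrame,
    reference_cells: list[str],
    sample_of_cell: pd.Series | None = None,
    half_window: int = 50,
    ea_threshold: float = 4.0,
) -> CNAProfile:
    """Full pipeline: filter, center, smooth in genomic order, summarize."""
    kept = aggregate_filter(matrix, threshold=ea_threshold)
    ordered = order_genes(gene_annotation, genes=kept)
    er = relative_expression(matrix, ordered["gene"].tolist())
    cna = moving_average_cna(er, ordered, half_window=half_window)
    return cna_stats(cna, reference_cells, sample_of_cell=sample_of_cell)
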