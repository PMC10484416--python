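"""Gene-signature module scoring, malignant-cell calling, NGS classification.

A module score compares the mean expression of a signature with the mean of
expression-matched control genes drawn from average-expression bins, so a
positive score means the signature is active above the cell's background.
Malignancy is a conjunction of up to three criteria (cluster annotation,
binary-marker scoring, CNA evidence); malignant cells with a positive NGS
score form the NGS+ class.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from .matrix import LAYER_NORMALIZED, PROTOCOL_UMI, ExpressionMatrix

NOT_APPLICABLE = "NA"


@dataclasses.dataclass
class GeneSignature:
    name: str
    genes: list[str]
    note: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")

    @classmethod
    def from_file(cls, path, name: str = "signature") -> "GeneSignature":
        genes = [ln.strip() for ln in open(path) if ln.strip()]
        return cls(name, genes)


def module_score(
    matrix: ExpressionMatrix,
    signature: GeneSignature,
    nbin: int = 30,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Signature score per cell: mean signature minus mean control expression.

    Genes are ranked by average expression across cells and split into
    ``nbin`` equal-frequency bins (ties broken by gene id). For each
    signature gene, ``n_ctrl`` control genes are sampled from its bin (with
    replacement if the bin is smaller). Deterministic given the seed.
    Signature genes absent from the matrix are dropped with a warning.
    """
    if matrix.layer != LAYER_NORMALIZED:
        raise ValueError("module_score expects a normalized matrix")
    present = [g for g in signature.genes if g in matrix.gene_ids]
    if not present:
        raise ValueError(
            f"no gene of signature {signature.name!r} is present in the matrix"
        )
    if len(present) < len(signature.genes):
        warnings.warn(
            f"{len(signature.genes) - len(present)} signature genes absent "
            "from the matrix; dropped"
        )
    x = matrix.values
    avg = x.mean(axis=1)
    # equal-frequency bins on the rank of average expression
    order = np.lexsort((x.index.to_numpy(), avg.to_numpy()))
    bin_of = pd.Series(np.empty(len(avg), dtype=int), index=x.index[order])
    bin_of.iloc[:] = (np.arange(len(avg)) * nbin) // len(avg)
    bin_of = bin_of.reindex(x.index)

    rng = np.random.default_rng(seed)
    bins = {b: x.index[bin_of == b].to_numpy() for b in range(nbin)}
    ctrl_rows = []
    for gene in present:
        pool = bins[int(bin_of[gene])]
        chosen = rng.choice(pool, size=n_ctrl, replace=len(pool) < n_ctrl)
        ctrl_rows.append(x.loc[chosen].to_numpy().mean(axis=0))
    sig_mean = x.loc[present].to_numpy().mean(axis=0)
    ctrl_mean = np.mean(ctrl_rows, axis=0)
    return pd.Series(sig_mean - ctrl_mean, index=x.columns, name=signature.name)


def call_malignant(
    cell_table: pd.DataFrame,
    protocol: str,
    has_reference: bool = True,
    any_normal_clusters: bool = True,
) -> pd.Series:
    """Concordant-criteria malignancy call per cell.

    ``cell_table`` must carry boolean columns ``criterion_a`` (cell not in
    an annotated normal cluster), ``criterion_b`` (cell not assigned normal
    by binary-marker scoring) and, where applicable, ``criterion_c`` (CNA
    signal/correlation evidence). Criterion c is skipped for droplet (10X)
    data and when no reference normal cells exist. If the dataset yielded
    no normal clusters at all, every cell is malignant.
    """
    if not any_normal_clusters:
        return pd.Series(True, index=cell_table.index, name="malignant")
    required = ["criterion_a", "criterion_b"]
    use_c = protocol != PROTOCOL_UMI and has_reference
    if use_c:
        required.append("criterion_c")
    missing = [c for c in required if c not in cell_table.columns]
    if missing:
        raise ValueError(f"cell table lacks criterion columns: {missing}")
    flag = cell_table["criterion_a"].astype(bool) & cell_table["criterion_b"].astype(bool)
    if use_c:
        flag &= cell_table["criterion_c"].astype(bool)
    return flag.rename("malignant")


def classify_ngs(scores: pd.Series, malignant: pd.Series) -> pd.Series:
    """NGS class per cell: NGS+ iff malignant and score > 0, NGS- otherwise
    for malignant cells (a score of exactly 0 is NGS-), NA for the rest."""
    malignant = malignant.reindex(scores.index).fillna(False).astype(bool)
    out = pd.Series(NOT_APPLICABLE, index=scores.index, name="ngs_class", dtype=object)
    out[malignant & (scores > 0)] = "NGS+"
    out[malignant & (scores <= 0)] = "NGS-"
    return out
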