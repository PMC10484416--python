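"""lncRNA -> NGS-gene regulatory-network assembly.

An edge is drawn when transcriptome and genome evidence agree: the pair's
Bayesian correlation exceeds 0.4 with BH-adjusted p < 0.05, and the lncRNA
has a DNA binding site with affinity > 100 in the gene's promoter. All
three conditions are strict inequalities.
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["lncRNA", "gene", "correlation", "adjusted_p", "dbs_affinity", "dataset"]


def build_network(
    correlations: pd.DataFrame,
    dbs_affinities: dict[tuple[str, str], float],
    corr_cut: float = 0.4,
    p_cut: float = 0.05,
    affinity_cut: float = 100.0,
    dataset: str = "",
) -> pd.DataFrame:
    """Edges passing the joint correlation + binding criterion.

    ``correlations`` needs columns lncRNA, gene, correlation, adjusted_p
    (one row per tested pair); ``dbs_affinities`` maps (lncRNA, gene) to
    the maximum DBS affinity in that gene's promoter. Pairs missing from
    ``dbs_affinities`` are treated as having no binding site (logged).
    The result is a deterministic function of the inputs, independent of
    row order.
    """
    required = {"lncRNA", "gene", "correlation", "adjusted_p"}
    missing = required - set(correlations.columns)
    if missing:
        raise ValueError(f"correlation table lacks columns: {sorted(missing)}")
    rows = []
    n_missing = 0
    for row in correlations.itertuples():
        if not (row.correlation > corr_cut and row.adjusted_p < p_cut):
            continue
        key = (row.lncRNA, row.gene)
        if key not in dbs_affinities:
            n_missing += 1
            continue
        affinity = dbs_affinities[key]
        if affinity > affinity_cut:
            rows.append(
                (row.lncRNA, row.gene, row.correlation, row.adjusted_p, affinity, dataset)
            )
    if n_missing:
        logger.info(
            "%d correlated pairs had no DBS call and were treated as non-binding",
            n_missing,
        )
    out = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return out.sort_values(["lncRNA", "gene"], kind="stable").reset_index(drop=True)


def glioma_count_summary(edge_tables: dict[str, pd.DataFrame]) -> pd.Series:
    """Per-lncRNA count of gliomas (datasets) in which it has >= 1 edge."""
    counts: dict[str, int] = {}
    for _name, edges in edge_tables.items():
        for lnc in edges["lncRNA"].unique():
            counts[lnc] = counts.get(lnc, 0) + 1
    return pd.Series(counts, name="n_gliomas").sort_index()


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def write_sif(edges: pd.DataFrame, path) -> None:
    """Cytoscape SIF: 'lncRNA regulates gene' per edge."""
    with open(path, "w") as fh:
        for row in edges.itertuples():
            fh.write(f"{row.lncRNA}\tregulates\t{row.gene}\n")
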