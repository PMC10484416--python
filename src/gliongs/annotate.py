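"""Differential expression, marker-based cluster annotation, binary markers.

Per-cluster DEGs come from Wilcoxon rank-sum tests (cluster vs rest) with
Benjamini-Hochberg adjustment; clusters are labelled as a normal cell type
when their DEGs are over-represented in that type's marker genes
(hypergeometric test, BH across cluster x type). Binary markers are DEGs
whose detection is nearly exclusive to one cluster, scored as
``f_in * (1 - f_out)`` on the detection fractions; cells anywhere in the
dataset can then be (re)assigned to a normal cluster by module-scoring its
binary markers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .malignancy import GeneSignature, module_score
from .matrix import LAYER_NORMALIZED, ExpressionMatrix
from .stats import bh_adjust

UNASSIGNED = "unassigned"


def find_degs(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    target_group=None,
    logfc_threshold: float = 0.5,
    alpha: float = 0.01,
    only_pos: bool = True,
) -> pd.DataFrame:
    """Wilcoxon rank-sum DEGs for each group (or one group) against the rest.

    logFC is the difference of mean log-expression (group minus rest, in
    the base of the input layer). A row is flagged ``is_deg`` when
    logFC > ``logfc_threshold`` and BH-adjusted p < ``alpha``; the
    adjustment family is all genes within one group comparison.
    """
    if matrix.layer != LAYER_NORMALIZED:
        raise ValueError("find_degs expects a normalized matrix")
    labels = labels.reindex(matrix.cell_ids)
    groups = [target_group] if target_group is not None else sorted(labels.dropna().unique())
    x = matrix.values.to_numpy()
    frames = []
    for group in groups:
        in_group = (labels == group).to_numpy()
        if in_group.sum() == 0:
            raise ValueError(f"group {group!r} absent from labels")
        if in_group.sum() < 3 or (~in_group).sum() < 3:
            raise ValueError(f"group {group!r} needs >= 3 cells on both sides")
        a, b = x[:, in_group], x[:, ~in_group]
        _, p = scipy.stats.mannwhitneyu(a, b, axis=1, alternative="two-sided", method="auto")
        logfc = a.mean(axis=1) - b.mean(axis=1)
        frame = pd.DataFrame(
            {
                "gene": matrix.gene_ids,
                "cluster": group,
                "logFC": logfc,
                "p": p,
                "adjusted_p": bh_adjust(p),
                "pct_in": (a > 0).mean(axis=1),
                "pct_out": (b > 0).mean(axis=1),
            }
        )
        if only_pos:
            frame = frame[frame["logFC"] > 0]
        frame["is_deg"] = (frame["logFC"] > logfc_threshold) & (frame["adjusted_p"] < alpha)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["cluster", "p", "gene"], kind="stable").reset_index(drop=True)


def deg_genes(deg_table: pd.DataFrame, cluster) -> list[str]:
    rows = deg_table[(deg_table["cluster"] == cluster) & deg_table["is_deg"]]
    return rows["gene"].tolist()


def annotate_normal_clusters(
    deg_table: pd.DataFrame,
    marker_db: dict[str, list[str]],
    universe: list[str],
    alpha: float = 0.05,
) -> pd.Series:
    """Cell-type label (or ``unassigned``) per cluster by marker enrichment.

    For each (cluster, type) pair a hypergeometric over-representation test
    asks whether the cluster's DEGs are enriched in the type's markers
    within ``universe`` (the genes tested for DE); p-values are BH-adjusted
    across all pairs and each cluster receives the best significant type
    (ties: smaller p, then lexicographic type name).
    """
    if not marker_db:
        raise ValueError("marker database is empty")
    universe_set = set(universe)
    clusters = sorted(deg_table["cluster"].unique())
    rows = []
    for cluster in clusters:
        degs = set(deg_genes(deg_table, cluster)) & universe_set
        for cell_type in sorted(marker_db):
            markers = set(marker_db[cell_type]) & universe_set
            k = len(degs & markers)
            if degs and markers:
                p = scipy.stats.hypergeom.sf(
                    k - 1, len(universe_set), len(markers), len(degs)
                )
            else:
                p = 1.0
            rows.append((cluster, cell_type, k, float(p)))
    table = pd.DataFrame(rows, columns=["cluster", "cell_type", "overlap", "p"])
    table["adjusted_p"] = bh_adjust(table["p"].to_numpy())

    labels = {}
    for cluster in clusters:
        sub = table[(table["cluster"] == cluster) & (table["adjusted_p"] < alpha)]
        if len(sub) == 0:
            labels[cluster] = UNASSIGNED
        else:
            best = sub.sort_values(["p", "cell_type"], kind="stable").iloc[0]
            labels[cluster] = best["cell_type"]
    return pd.Series(labels, name="cell_type")


def binary_scores(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    deg_table: pd.DataFrame,
    clusters: list | None = None,
    cutoff: float = 0.7,
) -> dict:
    """Binary markers per cluster: DEGs with ``f_in * (1 - f_out) > cutoff``.

    ``f_in``/``f_out`` are the fractions of cells inside/outside the
    cluster with expression > 0. Returns ``{cluster: [(gene, score), ...]}``
    keeping only genes above the cutoff (strict).
    """
    labels = labels.reindex(matrix.cell_ids)
    if clusters is None:
        clusters = sorted(deg_table["cluster"].unique())
    detected = matrix.values > 0
    out = {}
    for cluster in clusters:
        in_group = (labels == cluster).to_numpy()
        genes = deg_genes(deg_table, cluster)
        markers = []
        for gene in genes:
            row = detected.loc[gene].to_numpy()
            f_in = row[in_group].mean() if in_group.any() else 0.0
            f_out = row[~in_group].mean() if (~in_group).any() else 0.0
            score = float(f_in * (1.0 - f_out))
            if score > cutoff:
                markers.append((gene, score))
        out[cluster] = sorted(markers, key=lambda t: (-t[1], t[0]))
    return out


def score_cells_by_binary_markers(
    matrix: ExpressionMatrix,
    binary_marker_sets: dict,
    cutoff: float = 0.25,
    nbin: int = 30,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Assign each cell to the best-scoring normal cluster above ``cutoff``.

    Each cluster's binary markers form a signature whose module score is
    computed for every cell; a cell joins the highest-scoring cluster whose
    score exceeds the dataset-specific cutoff, otherwise stays unassigned
    (None).
    """
    scores = {}
    for cluster, markers in binary_marker_sets.items():
        genes = [g for g, _s in markers]
        if not genes:
            continue
        sig = GeneSignature(name=str(cluster), genes=genes)
        scores[cluster] = module_score(matrix, sig, nbin=nbin, n_ctrl=n_ctrl, seed=seed)
    assignment = pd.Series([None] * matrix.n_cells, index=matrix.cell_ids, dtype=object)
    if not scores:
        return assignment.rename("normal_cluster")
    frame = pd.DataFrame(scores)
    best = frame.idxmax(axis=1)
    best_score = frame.max(axis=1)
    assigned = best_score > cutoff
    assignment[assigned] = best[assigned]
    return assignment.rename("normal_cluster")
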