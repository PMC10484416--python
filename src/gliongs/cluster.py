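"""Highly-variable-gene selection, PCA embedding, and SNN graph clustering.

Cells are clustered by building a k-nearest-neighbour graph in PCA space,
converting it to a shared-nearest-neighbour (SNN) graph whose edge weights
are Jaccard similarities of neighbour sets (pruned below 1/15), and
optimizing modularity with the Louvain algorithm at a chosen resolution.
"""

from __future__ import annotations

import dataclasses
import random
import warnings

import igraph
import numpy as np
import pandas as pd
import scipy.sparse
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from .matrix import LAYER_NORMALIZED, ExpressionMatrix


@dataclasses.dataclass
class ClusterResult:
    labels: pd.Series            # cell id -> dense cluster id from 0
    modularity: float
    n_hvg: int | None = None
    n_pcs: int | None = None
    k_neighbors: int | None = None
    resolution: float | None = None

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def select_hvg(matrix: ExpressionMatrix, n: int = 2000) -> list[str]:
    """Top-``n`` highly variable genes by vst-style standardized variance.

    A lowess trend of log10 variance on log10 mean predicts each gene's
    expected variance; genes are ranked by the variance of their z-scores
    (observed minus mean over predicted sd, clipped at sqrt(n_cells)).
    Deterministic given the input.
    """
    if matrix.layer != LAYER_NORMALIZED:
        raise ValueError("select_hvg expects a normalized matrix")
    x = matrix.values.to_numpy()
    means = x.mean(axis=1)
    variances = x.var(axis=1, ddof=1)
    if n >= matrix.n_genes:
        if n > matrix.n_genes:
            warnings.warn(
                f"requested {n} HVGs but matrix has {matrix.n_genes} genes; "
                "returning all genes"
            )
        return matrix.gene_ids.tolist()

    varying = variances > 0
    log_mean = np.log10(means[varying] + 1e-12)
    log_var = np.log10(variances[varying])
    fit = lowess(log_var, log_mean, frac=0.3, return_sorted=True)
    expected_log_var = np.interp(log_mean, fit[:, 0], fit[:, 1])
    sd_exp = np.sqrt(10.0 ** expected_log_var)

    clip = np.sqrt(matrix.n_cells)
    z = (x[varying] - means[varying, None]) / sd_exp[:, None]
    np.clip(z, -clip, clip, out=z)
    std_var = np.full(matrix.n_genes, -np.inf)
    std_var[varying] = z.var(axis=1, ddof=1)

    # stable ranking: descending standardized variance, ties by gene id
    order = np.lexsort((matrix.gene_ids.to_numpy(), -std_var))
    return matrix.gene_ids[order[:n]].tolist()


def scale_and_pca(
    matrix: ExpressionMatrix,
    hvg: list[str],
    n_pcs: int = 20,
    clip: float = 10.0,
) -> pd.DataFrame:
    """Per-gene z-score (clipped at +/-``clip``) then PCA over cells.

    Returns a cells x PCs frame; components are ordered by decreasing
    explained variance.
    """
    missing = set(hvg) - set(matrix.gene_ids)
    if missing:
        raise ValueError(f"HVGs absent from matrix: {sorted(missing)[:5]}")
    x = matrix.values.loc[hvg].to_numpy()
    sd = x.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    np.clip(z, -clip, clip, out=z)
    if n_pcs > min(z.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds matrix rank bound {min(z.shape)}")
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=0)
    embedding = pca.fit_transform(z.T)
    return pd.DataFrame(
        embedding,
        index=matrix.cell_ids,
        columns=[f"PC{i+1}" for i in range(n_pcs)],
    )


def _snn_graph(embedding: np.ndarray, k: int, prune: float) -> scipy.sparse.coo_matrix:
    n = embedding.shape[0]
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, idx = nn.kneighbors(embedding)  # includes self at distance 0
    rows = np.repeat(np.arange(n), k)
    adj = scipy.sparse.csr_matrix(
        (np.ones(n * k), (rows, idx.ravel())), shape=(n, n)
    )
    shared = adj @ adj.T  # counts of shared neighbours
    shared = shared.tocoo()
    jaccard = shared.data / (2.0 * k - shared.data)
    keep = (jaccard >= prune) & (shared.row < shared.col)
    return scipy.sparse.coo_matrix(
        (jaccard[keep], (shared.row[keep], shared.col[keep])), shape=(n, n)
    )


def snn_cluster(
    embedding: pd.DataFrame,
    k: int = 20,
    resolution: float = 0.4,
    prune: float = 1.0 / 15.0,
    seed: int = 0,
) -> ClusterResult:
    """Louvain modularity clustering on the SNN graph of the embedding."""
    n = embedding.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    snn = _snn_graph(embedding.to_numpy(), k, prune)
    graph = igraph.Graph(
        n=n, edges=list(zip(snn.row.tolist(), snn.col.tolist())), directed=False
    )
    igraph.set_random_number_generator(random.Random(seed))
    part = graph.community_multilevel(
        weights=snn.data.tolist(), resolution=resolution
    )
    raw = np.asarray(part.membership)
    modularity = graph.modularity(part.membership, weights=snn.data.tolist())

    # dense relabelling: largest cluster first, ties by first cell index
    ids, counts = np.unique(raw, return_counts=True)
    first = np.array([np.argmax(raw == i) for i in ids])
    order = np.lexsort((first, -counts))
    remap = {int(ids[o]): new for new, o in enumerate(order)}
    labels = pd.Series([remap[int(v)] for v in raw], index=embedding.index, name="cluster")
    return ClusterResult(
        labels=labels,
        modularity=float(modularity),
        n_pcs=embedding.shape[1],
        k_neighbors=k,
        resolution=resolution,
    )
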