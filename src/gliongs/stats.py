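"""Statistical primitives: BH adjustment, Bayesian expression correlation,
Fisher enrichment of NGS+ cells, the DBS permutation test, and generic
hypergeometric gene-set enrichment.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.stats


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


@dataclasses.dataclass
class CorrelationRecord:
    x_name: str
    y_name: str
    correlation: float
    p: float
    n: int
    defined: bool = True


def bayesian_correlation(
    x,
    y,
    totals,
    prior: float = 1.0,
    n_genes: int | None = None,
    x_name: str = "x",
    y_name: str = "y",
) -> CorrelationRecord:
    """Correlation of posterior-mean expression rates of two genes.

    Each cell's counts are modelled as multinomial over genes with a
    symmetric Dirichlet prior (pseudocount ``prior``); the posterior-mean
    rate of a gene in cell j is ``(count_j + prior) / (total_j + prior *
    n_genes)``. The statistic is the Pearson correlation of the two rate
    vectors, which converges to the plain Pearson correlation of rates as
    sequencing depth grows. The p-value is from the t-statistic of the
    correlation at n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    totals = np.asarray(totals, dtype=float)
    if not (x.shape == y.shape == totals.shape):
        raise ValueError("x, y, totals must share the same cells")
    n = x.size
    if n < 10:
        raise ValueError(f"need >= 10 cells, got {n}")
    if n_genes is None:
        n_genes = 1
    denom = totals + prior * n_genes
    rx = (x + prior) / denom
    ry = (y + prior) / denom
    if np.allclose(rx.std(), 0) or np.allclose(ry.std(), 0):
        return CorrelationRecord(x_name, y_name, np.nan, 1.0, n, defined=False)
    r, _ = scipy.stats.pearsonr(rx, ry)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * scipy.stats.t.sf(abs(t), df=n - 2))
    return CorrelationRecord(x_name, y_name, r, p, n)


def correlate_pairs(
    counts: pd.DataFrame,
    lnc_genes: list[str],
    target_genes: list[str],
    prior: float = 1.0,
) -> pd.DataFrame:
    """Bayesian correlation for every (lncRNA, target) pair, BH across pairs."""
    totals = counts.sum(axis=0).to_numpy()
    n_genes = counts.shape[0]
    rows = []
    for lnc in lnc_genes:
        for gene in target_genes:
            rec = bayesian_correlation(
                counts.loc[lnc].to_numpy(),
                counts.loc[gene].to_numpy(),
                totals,
                prior=prior,
                n_genes=n_genes,
                x_name=lnc,
                y_name=gene,
            )
            rows.append((lnc, gene, rec.correlation, rec.p, rec.defined))
    out = pd.DataFrame(rows, columns=["lncRNA", "gene", "correlation", "p", "defined"])
    out["adjusted_p"] = bh_adjust(out["p"].to_numpy())
    return out


def fisher_ngs_enrichment(
    group_labels: pd.Series,
    ngs_class: pd.Series,
    background: list | pd.Index | None = None,
    group: str = "Scissor+",
    side: str = "greater",
) -> tuple[float, float]:
    """One-sided Fisher exact test: is a cell group enriched in NGS+ cells?

    The 2x2 table crosses membership of ``group`` (vs the rest of
    ``background``) with NGS class (NGS+ vs NGS-). ``background`` defaults
    to all cells with an NGS class; passing e.g. the malignant cell set
    reproduces a background-vs-group construction.
    Returns (odds ratio, p).
    """
    if side not in ("greater", "less"):
        raise ValueError("side must be 'greater' or 'less'")
    cells = pd.Index(background) if background is not None else ngs_class.index
    cells = cells.intersection(ngs_class.dropna().index)
    in_group = group_labels.reindex(cells) == group
    if not in_group.any():
        raise ValueError(f"group {group!r} is empty within the background")
    pos = ngs_class.reindex(cells) == "NGS+"
    table = [
        [int((in_group & pos).sum()), int((in_group & ~pos).sum())],
        [int((~in_group & pos).sum()), int((~in_group & ~pos).sum())],
    ]
    odds, p = scipy.stats.fisher_exact(table, alternative=side)
    return float(odds), float(p)


def permutation_dbs_test(
    n_genes: int,
    n_with_dbs: int,
    sample_size: int,
    observed: int,
    n_perm: int = 1_000_000,
    seed: int = 0,
    plus_one: bool = True,
) -> float:
    """Empirical p that >= ``observed`` of ``sample_size`` random genes carry a DBS.

    Genes are sampled uniformly without replacement from a universe of
    ``n_genes`` of which ``n_with_dbs`` carry a binding site; the number of
    carriers per resample is therefore a hypergeometric draw, and the test
    counts resamples with at least the observed number. With ``plus_one``
    the estimate is (1 + hits) / (n_perm + 1); otherwise the plain ratio
    hits / n_perm.
    """
    if not 0 <= observed <= sample_size:
        raise ValueError("need 0 <= observed <= sample_size")
    if not sample_size <= n_genes or not 0 <= n_with_dbs <= n_genes:
        raise ValueError("need sample_size <= n_genes and 0 <= n_with_dbs <= n_genes")
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if observed == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(n_with_dbs, n_genes - n_with_dbs, sample_size, size=n_perm)
    hits = int((draws >= observed).sum())
    if plus_one:
        return (1 + hits) / (n_perm + 1)
    return hits / n_perm


def gene_set_enrichment(
    deg_list: list[str],
    gene_sets: dict[str, list[str]],
    universe: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the DEG list."""
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    degs = set(deg_list) & universe_set
    if set(deg_list) - universe_set:
        raise ValueError("deg_list contains genes outside the universe")
    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe_set
        if not in_universe:
            warnings.warn(f"gene set {name!r} is disjoint from the universe; skipped")
            continue
        k = len(degs & in_universe)
        p = scipy.stats.hypergeom.sf(
            k - 1, len(universe_set), len(in_universe), len(degs)
        )
        rows.append((name, len(in_universe), k, float(p)))
    out = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"])
    if len(out):
        out["adjusted_p"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["adjusted_p"] < alpha
        out = out.sort_values(["p", "gene_set"], kind="stable").reset_index(drop=True)
    return out
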