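import numpy as np
import pandas as pd
import pytest
import scipy.stats

from gliongs.annotate import (
    UNASSIGNED,
    annotate_normal_clusters,
    binary_scores,
    deg_genes,
    find_degs,
    score_cells_by_binary_markers,
)
from gliongs.matrix import ExpressionMatrix
from oracles import exact_wilcoxon_p


def normalized_matrix(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i:03d}" for i in range(values.shape[0])]
    cells = cells or [f"c{j:03d}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=cells), "tpm", layer="normalized"
    )


def labels_for(matrix, groups):
    return pd.Series(groups, index=matrix.cell_ids)


class TestFindDegs:
    def test_p_matches_exhaustive_enumeration_on_tiny_groups(self, rng):
        for n1, n2 in [(3, 3), (4, 4), (5, 8), (8, 8)]:
            x = rng.normal(size=(4, n1 + n2))
            x += rng.uniform(0, 1e-6, size=x.shape)  # guarantee no ties
            m = normalized_matrix(np.abs(x) + 1)
            labels = labels_for(m, ["a"] * n1 + ["b"] * n2)
            table = find_degs(m, labels, target_group="a", only_pos=False)
            for row in table.itertuples():
                vals = m.values.loc[row.gene]
                expected = exact_wilcoxon_p(vals[:n1], vals[n1:])
                assert row.p == pytest.approx(expected, rel=1e-9), (n1, n2)

    def test_permuted_labels_yield_no_degs(self):
        clean = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = np.abs(rng.normal(2, 1, size=(100, 60)))
            m = normalized_matrix(x)
            labels = labels_for(m, rng.permutation(["a"] * 30 + ["b"] * 30))
            table = find_degs(m, labels, target_group="a")
            clean += int(table["is_deg"].sum() == 0)
        assert clean >= 19

    def test_planted_fourfold_gene_flagged(self, rng):
        x = np.abs(rng.normal(2, 0.5, size=(50, 400)))
        x[10, :200] *= 4
        m = normalized_matrix(x)
        labels = labels_for(m, ["hot"] * 200 + ["rest"] * 200)
        table = find_degs(m, labels, target_group="hot")
        assert "g010" in deg_genes(table, "hot")

    def test_logfc_is_difference_of_log_means_and_table_invariants(self, rng):
        x = np.abs(rng.normal(2, 1, size=(30, 40)))
        m = normalized_matrix(x)
        labels = labels_for(m, ["a"] * 20 + ["b"] * 20)
        table = find_degs(m, labels, only_pos=False)
        row = table[(table["gene"] == "g005") & (table["cluster"] == "a")].iloc[0]
        assert row["logFC"] == pytest.approx(x[5, :20].mean() - x[5, 20:].mean())
        assert (table["adjusted_p"] >= table["p"] - 1e-12).all()
        assert np.isfinite(table["logFC"]).all()
        assert table.groupby(["gene", "cluster"]).size().max() == 1

    def test_absent_group_and_tiny_group_rejected(self, rng):
        m = normalized_matrix(np.abs(rng.normal(2, 1, size=(10, 10))))
        labels = labels_for(m, ["a"] * 5 + ["b"] * 5)
        with pytest.raises(ValueError, match="absent"):
            find_degs(m, labels, target_group="zz")
        labels2 = labels_for(m, ["a"] * 2 + ["b"] * 8)
        with pytest.raises(ValueError, match=">= 3"):
            find_degs(m, labels2, target_group="a")


def deg_table_from(rows):
    frame = pd.DataFrame(rows, columns=["gene", "cluster"])
    frame["logFC"] = 1.0
    frame["p"] = 1e-6
    frame["adjusted_p"] = 1e-5
    frame["is_deg"] = True
    return frame


class TestAnnotateClusters:
    def test_exact_marker_cluster_assigned_with_tiny_p(self):
        universe = [f"g{i}" for i in range(200)]
        markers = {"oligodendrocyte": universe[:15], "astrocyte": universe[50:65]}
        table = deg_table_from([(g, 0) for g in universe[:15]])
        labels = annotate_normal_clusters(table, markers, universe)
        assert labels[0] == "oligodendrocyte"
        p = scipy.stats.hypergeom.sf(14, 200, 15, 15)
        assert p < 1e-6  # the assignment rides on an overwhelming enrichment

    def test_disjoint_degs_unassigned(self):
        universe = [f"g{i}" for i in range(100)]
        markers = {"astrocyte": universe[:10]}
        table = deg_table_from([(g, 0) for g in universe[50:60]])
        assert annotate_normal_clusters(table, markers, universe)[0] == UNASSIGNED

    def test_tied_types_break_lexicographically(self):
        universe = [f"g{i}" for i in range(100)]
        shared = universe[:10]
        markers = {"zeta": shared, "alpha": shared}
        table = deg_table_from([(g, 0) for g in shared])
        assert annotate_normal_clusters(table, markers, universe)[0] == "alpha"

    def test_empty_marker_db_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            annotate_normal_clusters(deg_table_from([("g1", 0)]), {}, ["g1"])


class TestBinaryScores:
    def test_score_endpoints(self):
        x = np.zeros((2, 20))
        x[0, :10] = 5.0          # exclusive to cluster a
        x[1, :] = 5.0            # uniform everywhere
        m = normalized_matrix(x)
        labels = labels_for(m, ["a"] * 10 + ["b"] * 10)
        table = deg_table_from([("g000", "a"), ("g001", "a")])
        scores = dict(binary_scores(m, labels, table)["a"])
        assert scores.get("g000") == pytest.approx(1.0)
        assert "g001" not in scores  # f(1-f) <= 0.25 < 0.7

    def test_undetected_gene_scores_zero_and_range(self, rng):
        x = np.abs(rng.normal(1, 1, size=(5, 30)))
        x[2] = 0.0
        m = normalized_matrix(x)
        labels = labels_for(m, ["a"] * 15 + ["b"] * 15)
        table = deg_table_from([(f"g{i:03d}", "a") for i in range(5)])
        out = binary_scores(m, labels, table, cutoff=-0.1)
        scores = dict(out["a"])
        assert scores["g002"] == 0.0
        assert all(0.0 <= s <= 1.0 for s in scores.values())

    def test_planted_exclusive_markers_recovered_at_cutoff(self, rng):
        n_cells = 200
        x = np.abs(rng.normal(1, 0.5, size=(40, n_cells)))
        in_a = np.arange(n_cells) < 100
        for g in range(5):  # detection ~0.95 inside, ~0.03 outside
            row = np.where(rng.uniform(size=n_cells) < 0.03, 1.0, 0.0)
            row[in_a] = np.where(rng.uniform(size=100) < 0.95, 1.0, 0.0)
            x[g] = row
        m = normalized_matrix(x)
        labels = labels_for(m, ["a"] * 100 + ["b"] * 100)
        table = deg_table_from([(f"g{i:03d}", "a") for i in range(5)])
        markers = [g for g, _s in binary_scores(m, labels, table, cutoff=0.7)["a"]]
        assert set(markers) == {f"g{i:03d}" for i in range(5)}


class TestScoreCellsByBinaryMarkers:
    def _dataset(self, rng):
        # two normal types with exclusive markers + unstructured cells
        n = 300
        x = np.abs(rng.normal(1, 0.3, size=(60, n)))
        type_a = np.arange(n) < 100
        type_b = (np.arange(n) >= 100) & (np.arange(n) < 200)
        x[:5][:, type_a] += 4.0
        x[5:10][:, type_b] += 4.0
        m = normalized_matrix(x)
        sets = {
            "a": [(f"g{i:03d}", 0.9) for i in range(5)],
            "b": [(f"g{i:03d}", 0.9) for i in range(5, 10)],
        }
        return m, sets, type_a, type_b

    def test_cells_assigned_to_their_planted_type(self, rng):
        m, sets, type_a, type_b = self._dataset(rng)
        out = score_cells_by_binary_markers(m, sets, cutoff=0.25, seed=0)
        assert (out.to_numpy()[type_a] == "a").mean() > 0.95
        assert (out.to_numpy()[type_b] == "b").mean() > 0.95
        unstructured = ~(type_a | type_b)
        assert (pd.isna(out.to_numpy()[unstructured])).mean() > 0.9

    def test_infinite_cutoff_assigns_nobody(self, rng):
        m, sets, _a, _b = self._dataset(rng)
        out = score_cells_by_binary_markers(m, sets, cutoff=np.inf, seed=0)
        assert out.isna().all()

    def test_cell_exceeding_two_sets_takes_higher_score(self, rng):
        # one cell clears both cutoffs; assignment goes to the higher score
        x = np.abs(rng.normal(1, 0.1, size=(40, 50)))
        x[0, 0] = 8.0   # "high" set marker, strongly expressed in cell 0
        x[1, 0] = 4.0   # "low" set marker, above cutoff but weaker
        m = normalized_matrix(x)
        sets = {"high": [("g000", 0.9)], "low": [("g001", 0.9)]}
        out = score_cells_by_binary_markers(m, sets, cutoff=0.25, nbin=5, seed=0)
        assert out.iloc[0] == "high"
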