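import numpy as np
import pandas as pd
import pytest

from gliongs.cna import (
    aggregate_filter,
    cna_malignant_flag,
    cna_stats,
    moving_average_cna,
    order_genes,
    relative_expression,
    run_cna,
)
from gliongs.matrix import ExpressionMatrix
from oracles import windowed_mean


def annotation(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "start"])


class TestOrderGenes:
    def test_karyotype_order_not_lexicographic(self):
        ann = annotation(
            [("a", "chr10", 5), ("b", "chr2", 5), ("c", "chr2", 1), ("d", "chrX", 1)]
        )
        out = order_genes(ann)
        assert out["gene"].tolist() == ["c", "b", "a", "d"]

    def test_tie_broken_by_gene_id_and_shuffle_invariance(self, rng):
        rows = [(g, "chr1", 100) for g in ["zz", "aa", "mm"]]
        ann = annotation(rows)
        out = order_genes(ann)
        assert out["gene"].tolist() == ["aa", "mm", "zz"]
        shuffled = ann.sample(frac=1.0, random_state=3)
        assert order_genes(shuffled)["gene"].tolist() == out["gene"].tolist()

    def test_missing_coordinates_excluded_with_warning(self):
        ann = annotation([("a", "chr1", 1), ("b", None, None)])
        with pytest.warns(UserWarning, match="excluded"):
            out = order_genes(ann)
        assert out["gene"].tolist() == ["a"]


class TestAggregateFilter:
    @pytest.mark.parametrize(
        "mean_tpm,kept", [(0.0, False), (15.0, False), (31.0, True)]
    )
    def test_ea_threshold_strict(self, mean_tpm, kept):
        values = pd.DataFrame(
            {"c0": [mean_tpm], "c1": [mean_tpm]}, index=["g0"]
        )
        m = ExpressionMatrix(values, "tpm")
        assert (aggregate_filter(m) == ["g0"]) is kept


class TestRelativeExpression:
    def test_rows_centered_and_constant_gene_zero(self, rng):
        tpm = pd.DataFrame(
            rng.uniform(0, 100, size=(5, 4)),
            index=[f"g{i}" for i in range(5)],
            columns=[f"c{j}" for j in range(4)],
        )
        tpm.iloc[2] = 50.0
        er = relative_expression(ExpressionMatrix(tpm, "tpm"), tpm.index.tolist())
        np.testing.assert_allclose(er.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(er.iloc[2], 0.0, atol=1e-12)

    def test_hand_computed_three_by_three(self):
        tpm = pd.DataFrame(
            [[0.0, 10.0, 30.0], [10.0, 10.0, 10.0], [30.0, 0.0, 0.0]],
            index=["g0", "g1", "g2"],
            columns=["c0", "c1", "c2"],
        )
        er = relative_expression(ExpressionMatrix(tpm, "tpm"), ["g0", "g1", "g2"])
        e = np.log2(tpm.to_numpy() / 10 + 1)
        np.testing.assert_allclose(er.to_numpy(), e - e.mean(axis=1, keepdims=True))


class TestMovingAverage:
    def _ann(self, genes, chrom="chr1"):
        return annotation([(g, chrom, i * 10) for i, g in enumerate(genes)])

    def test_constant_column_unchanged(self):
        genes = [f"g{i:03d}" for i in range(120)]
        er = pd.DataFrame({"c0": np.full(120, 0.7)}, index=genes)
        out = moving_average_cna(er, self._ann(genes))
        np.testing.assert_allclose(out["c0"], 0.7)

    def test_interior_divisor_is_101(self):
        genes = [f"g{i:03d}" for i in range(201)]
        er = pd.DataFrame({"c0": np.zeros(201)}, index=genes)
        er.iloc[100] = 1.0  # spike reaching only interior windows
        out = moving_average_cna(er, self._ann(genes))
        assert out["c0"].iloc[100] == pytest.approx(1.0 / 101)

    def test_matches_bruteforce_window_mean(self, rng):
        n = 500
        genes = [f"g{i:03d}" for i in range(n)]
        er = pd.DataFrame(
            rng.normal(size=(n, 7)), index=genes,
            columns=[f"c{j}" for j in range(7)],
        )
        out = moving_average_cna(er, self._ann(genes))
        np.testing.assert_allclose(
            out.to_numpy(), windowed_mean(er.to_numpy(), 50), atol=1e-12
        )

    def test_windows_do_not_cross_chromosomes(self, rng):
        genes1 = [f"a{i:02d}" for i in range(60)]
        genes2 = [f"b{i:02d}" for i in range(60)]
        ann = pd.concat([self._ann(genes1, "chr1"), self._ann(genes2, "chr2")])
        er = pd.DataFrame(
            np.vstack([np.zeros((60, 1)), np.ones((60, 1))]),
            index=genes1 + genes2, columns=["c0"],
        )
        out = moving_average_cna(er, ann)
        np.testing.assert_allclose(out.loc[genes1, "c0"], 0.0)
        np.testing.assert_allclose(out.loc[genes2, "c0"], 1.0)

    def test_step_profile_smooths_to_ramp(self):
        genes = [f"g{i:03d}" for i in range(400)]
        profile = np.zeros(400)
        profile[100:300] = 1.0
        er = pd.DataFrame({"c0": profile}, index=genes)
        out = moving_average_cna(er, self._ann(genes))["c0"].to_numpy()
        expected = windowed_mean(profile[:, None], 50).ravel()
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert np.all(np.diff(out[60:160]) >= -1e-12)  # monotone ramp up

    def test_tiny_chromosome_passed_through_with_warning(self):
        ann = annotation([("a", "chr1", 1)])
        er = pd.DataFrame({"c0": [0.4]}, index=["a"])
        with pytest.warns(UserWarning, match="unsmoothed"):
            out = moving_average_cna(er, ann)
        assert out["c0"].iloc[0] == 0.4


class TestCnaStats:
    def _cna(self, rng, n_genes=80, n_ref=10, n_tumor=10, shift=0.0):
        genes = [f"g{i:02d}" for i in range(n_genes)]
        ref = rng.normal(0, 0.01, size=(n_genes, n_ref))
        tumor = rng.normal(0, 0.01, size=(n_genes, n_tumor))
        tumor[: n_genes // 2] += shift
        cols = [f"ref{i}" for i in range(n_ref)] + [f"tum{i}" for i in range(n_tumor)]
        return (
            pd.DataFrame(np.hstack([ref, tumor]), index=genes, columns=cols),
            [f"ref{i}" for i in range(n_ref)],
        )

    def test_reference_cell_at_baseline_has_zero_signal(self):
        cna = pd.DataFrame(
            {"ref0": [0.1, -0.2], "ref1": [0.1, -0.2], "tum0": [0.5, 0.5]},
            index=["g0", "g1"],
        )
        prof = cna_stats(cna, ["ref0", "ref1"])
        assert prof.signal["ref0"] == pytest.approx(0.0)
        assert (prof.signal >= 0).all()

    def test_shared_shift_gives_high_correlation(self, rng):
        cna, ref = self._cna(rng, shift=0.5)
        prof = cna_stats(cna, ref)
        tumor = [c for c in cna.columns if c.startswith("tum")]
        assert (prof.correlation[tumor] > 0.4).all()
        assert (prof.signal[tumor] > prof.signal[ref].max()).all()

    def test_no_reference_cells_is_an_error(self, rng):
        cna, _ref = self._cna(rng)
        with pytest.raises(ValueError, match="reference"):
            cna_stats(cna, [])

    def test_leave_one_out_excludes_self(self, rng):
        # with exactly one non-reference cell, its LOO profile is undefined
        cna, ref = self._cna(rng, n_tumor=1, shift=0.5)
        prof = cna_stats(cna, ref)
        assert np.isnan(prof.correlation["tum0"])
        prof2 = cna_stats(cna, ref, leave_one_out=False)
        assert prof2.correlation["tum0"] == pytest.approx(1.0)


class TestMalignantFlag:
    def test_strict_thresholds(self, rng):
        cna, ref = self._make(rng)
        prof = cna_stats(cna, ref)
        prof.signal[:] = 0.02
        prof.correlation[:] = 0.9
        assert not cna_malignant_flag(prof).any()  # signal exactly at cut
        prof.signal[:] = 0.05
        assert cna_malignant_flag(prof).all()
        prof.correlation[:] = 0.4
        assert not cna_malignant_flag(prof).any()  # correlation at cut

    def _make(self, rng):
        genes = [f"g{i}" for i in range(20)]
        cols = ["ref0", "ref1", "t0", "t1"]
        return (
            pd.DataFrame(rng.normal(size=(20, 4)), index=genes, columns=cols),
            ["ref0", "ref1"],
        )


class TestRunCnaOnSimulation:
    def test_recovers_planted_arm_gain(self, sim_dataset):
        _config, matrix, truth = sim_dataset
        cells = truth.cell_table
        reference = cells.index[~cells["malignant"]].tolist()
        ann = truth.gene_annotation[["gene", "chrom", "start"]]
        profile = run_cna(matrix, ann, reference)
        flags = cna_malignant_flag(profile)
        mal = cells["malignant"]
        sensitivity = flags[mal].mean()
        specificity = 1.0 - flags[~mal].mean()
        assert sensitivity >= 0.9
        assert specificity >= 0.95
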