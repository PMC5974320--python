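import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tomoloc.io_formats import CqTable, SegmentTable
from tomoloc.normalization import (
    SizeFactors, apply_size_factors, compute_size_factors, cq_to_fractions,
    filter_low_expression, global_mean_normalize, to_fractions,
)


def _cq(cols: dict, segments, reps, efficiency=None) -> CqTable:
    return CqTable(pd.DataFrame(cols, index=["anc"]), segments, reps,
                   efficiency or {})


def _table(cols: dict, segments, reps, index, kind="rna") -> SegmentTable:
    return SegmentTable(pd.DataFrame(cols, index=index), segments, reps, kind)


class TestCqToFractions:
    def test_equal_cq_gives_uniform(self, flat_cq_table):
        frac = cq_to_fractions(flat_cq_table, "anc1")
        np.testing.assert_allclose(frac, np.full(5, 0.2))

    @pytest.mark.parametrize("cqs,expected", [
        ([10.0, 11.0], [2 / 3, 1 / 3]),     # one cycle = one doubling
        ([10.0, 12.0], [0.8, 0.2]),         # two cycles = 4:1
    ])
    def test_cycle_ratios(self, cqs, expected):
        cq = _cq({"A_r1": [cqs[0]], "B_r1": [cqs[1]]}, ["A", "B"], [1])
        np.testing.assert_allclose(cq_to_fractions(cq, "anc"), expected)

    def test_plate_offset_cancels_between_replicates(self):
        cq = _cq({"A_r1": [10.0], "B_r1": [11.0],
                  "A_r2": [15.0], "B_r2": [16.0]}, ["A", "B"], [1, 2])
        np.testing.assert_allclose(cq_to_fractions(cq, "anc"), [2 / 3, 1 / 3])

    def test_missing_segment_errors(self):
        cq = _cq({"A_r1": [10.0], "B_r1": [np.nan]}, ["A", "B"], [1])
        with pytest.raises(ValueError, match="missing"):
            cq_to_fractions(cq, "anc")


class TestComputeSizeFactors:
    def test_consistent_anchor_gives_unit_factors(self):
        # RNA-seq fractions equal qPCR fractions -> all factors 1
        counts = _table({"A_r1": [40.0], "B_r1": [20.0]}, ["A", "B"], [1], ["anc"])
        cq = _cq({"A_r1": [10.0], "B_r1": [11.0]}, ["A", "B"], [1])
        f = compute_size_factors(counts, cq)
        np.testing.assert_allclose(f.data[1].to_numpy(), [1.0, 1.0])

    def test_distorted_anchor(self):
        # q = [0.5, 0.5], r = [0.8, 0.2] -> raw [0.625, 2.5] -> rescaled [0.5, 2]
        counts = _table({"A_r1": [80.0], "B_r1": [20.0]}, ["A", "B"], [1], ["anc"])
        cq = _cq({"A_r1": [10.0], "B_r1": [10.0]}, ["A", "B"], [1])
        f = compute_size_factors(counts, cq)
        np.testing.assert_allclose(f.data[1].to_numpy(), [0.5, 2.0])

    def test_median_over_anchors(self):
        # three anchors, one outlier: median ratio chosen per segment
        data = pd.DataFrame({"A_r1": [40.0, 40.0, 10.0], "B_r1": [20.0, 20.0, 50.0]},
                            index=["a1", "a2", "a3"])
        counts = SegmentTable(data, ["A", "B"], [1], "rna")
        cq_data = pd.DataFrame({"A_r1": [10.0, 10.0, 10.0],
                                "B_r1": [11.0, 11.0, 11.0]},
                               index=["a1", "a2", "a3"])
        cq = CqTable(cq_data, ["A", "B"], [1])
        f = compute_size_factors(counts, cq)
        np.testing.assert_allclose(f.data[1].to_numpy(), [1.0, 1.0])

    def test_zero_count_anchor_excluded(self, caplog):
        data = pd.DataFrame({"A_r1": [40.0, 0.0], "B_r1": [20.0, 10.0]},
                            index=["a1", "a2"])
        counts = SegmentTable(data, ["A", "B"], [1], "rna")
        cq = CqTable(pd.DataFrame({"A_r1": [10.0, 10.0], "B_r1": [11.0, 11.0]},
                                  index=["a1", "a2"]), ["A", "B"], [1])
        f = compute_size_factors(counts, cq)
        np.testing.assert_allclose(f.data[1].to_numpy(), [1.0, 1.0])

    def test_no_usable_anchor_errors(self):
        counts = _table({"A_r1": [0.0], "B_r1": [10.0]}, ["A", "B"], [1], ["anc"])
        cq = _cq({"A_r1": [10.0], "B_r1": [10.0]}, ["A", "B"], [1])
        with pytest.raises(ValueError, match="no usable anchor"):
            compute_size_factors(counts, cq)

    def test_geometric_mean_is_one(self):
        counts = _table({"A_r1": [70.0], "B_r1": [10.0]}, ["A", "B"], [1], ["anc"])
        cq = _cq({"A_r1": [10.0], "B_r1": [11.5]}, ["A", "B"], [1])
        f = compute_size_factors(counts, cq)
        assert stats.gmean(f.data[1].to_numpy()) == pytest.approx(1.0, abs=1e-12)


class TestApplyFilterFractions:
    def test_unit_factors_identity(self, small_rna_table):
        f = SizeFactors(pd.DataFrame({1: np.ones(5), 2: np.ones(5)},
                                     index=list("ABCDE")))
        out = apply_size_factors(small_rna_table, f)
        pd.testing.assert_frame_equal(out.data, small_rna_table.data)

    def test_factor_scales_only_its_segment(self, small_rna_table):
        f = SizeFactors(pd.DataFrame({1: [2.0, 1, 1, 1, 1], 2: np.ones(5)},
                                     index=list("ABCDE")))
        out = apply_size_factors(small_rna_table, f)
        assert (out.data["A_r1"] == 2 * small_rna_table.data["A_r1"]).all()
        assert (out.data["B_r1"] == small_rna_table.data["B_r1"]).all()
        assert (out.data["A_r2"] == small_rna_table.data["A_r2"]).all()

    @pytest.mark.parametrize("mean,kept", [(14.9, False), (15.0, True),
                                           (0.0, False)])
    def test_filter_boundary_strict(self, mean, kept):
        cols = {f"{s}_r1": [mean] for s in "ABCDE"}
        table = _table(cols, list("ABCDE"), [1], ["g1"])
        out = filter_low_expression(table, threshold=15.0)
        assert ("g1" in out.gene_ids) is kept

    def test_filter_threshold_zero_keeps_all(self, small_rna_table):
        out = filter_low_expression(small_rna_table, threshold=0.0)
        assert out.gene_ids == small_rna_table.gene_ids

    def test_fractions_sum_to_one(self, small_rna_table):
        prof = to_fractions(small_rna_table)
        for frame in list(prof.replicates.values()) + [prof.consensus]:
            np.testing.assert_allclose(frame.sum(axis=1), 1.0, atol=1e-9)

    def test_fraction_values(self):
        table = _table({"A_r1": [60.0], "B_r1": [20.0], "C_r1": [10.0],
                        "D_r1": [5.0], "E_r1": [5.0]}, list("ABCDE"), [1], ["g"])
        prof = to_fractions(table)
        np.testing.assert_allclose(prof.consensus.loc["g"],
                                   [0.6, 0.2, 0.1, 0.05, 0.05])

    def test_identical_replicates_consensus(self):
        cols = {f"{s}_r{r}": [v] for r in (1, 2)
                for s, v in zip("ABCDE", [50, 20, 15, 10, 5])}
        table = _table(cols, list("ABCDE"), [1, 2], ["g"])
        prof = to_fractions(table)
        pd.testing.assert_series_equal(prof.consensus.loc["g"],
                                       prof.replicates[1].loc["g"])


class TestGlobalMeanNormalize:
    def test_column_means_become_one(self, rng):
        data = pd.DataFrame(
            rng.lognormal(0, 1, size=(20, 4)) * np.array([1, 2, 4, 8]),
            index=[f"p{i}" for i in range(20)],
            columns=["A_r1", "B_r1", "C_r1", "D_r1"])
        table = SegmentTable(data, list("ABCD"), [1], "protein")
        out = global_mean_normalize(table)
        np.testing.assert_allclose(out.data.mean(axis=0), 1.0)

    def test_single_protein_becomes_all_ones(self):
        table = _table({"A_r1": [3.0], "B_r1": [7.0], "C_r1": [1.0],
                        "D_r1": [9.0]}, list("ABCD"), [1], ["p"], "protein")
        np.testing.assert_allclose(global_mean_normalize(table).data.loc["p"], 1.0)

    def test_zero_mean_column_errors(self):
        table = _table({"A_r1": [0.0], "B_r1": [1.0], "C_r1": [1.0],
                        "D_r1": [1.0]}, list("ABCD"), [1], ["p"], "protein")
        with pytest.raises(ValueError, match="zero mean"):
            global_mean_normalize(table)
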