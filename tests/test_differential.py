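import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zga import differential as D
from zga.genome import CountMatrix, GenomeBuild, TranscriptUnit, transcripts_frame

from conftest import make_fragments


def _cm(array, conditions, index=None):
    df = pd.DataFrame(np.asarray(array),
                      index=index or [f"g{i}" for i in range(len(array))],
                      columns=[f"s{i}" for i in range(np.asarray(array).shape[1])])
    meta = pd.DataFrame({"condition": conditions,
                         "replicate": [str(i) for i in range(df.shape[1])]},
                        index=df.columns)
    return CountMatrix(df, meta)


class TestReferenceSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        cm = _cm([[10, 10], [20, 20], [5, 5]], ["a", "b"])
        sf = D.reference_size_factors(cm, {"g0", "g1", "g2"})
        assert sf.tolist() == pytest.approx([1.0, 1.0])

    def test_doubled_sample_gets_double_factor(self):
        cm = _cm([[10, 20], [30, 60], [7, 14]], ["a", "b"])
        sf = D.reference_size_factors(cm, {"g0", "g1", "g2"})
        assert sf["s1"] / sf["s0"] == pytest.approx(2.0)

    def test_change_outside_reference_ignored(self):
        base = np.array([[10, 10], [30, 30], [50, 50], [100, 1000]])
        cm = _cm(base, ["a", "b"])
        sf = D.reference_size_factors(cm, {"g0", "g1", "g2"})
        assert sf.tolist() == pytest.approx([1.0, 1.0])

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(5, 500, size=(30, 4))
        cm = _cm(counts, ["a", "a", "b", "b"])
        ref = {f"g{i}" for i in range(30)}
        sf = D.reference_size_factors(cm, ref)
        scaled = counts.copy()
        scaled[:, 2] *= 3
        sf2 = D.reference_size_factors(_cm(scaled, ["a", "a", "b", "b"]), ref)
        # the geometric-mean reference moves with the scaled sample, so
        # equivariance holds exactly on factor ratios
        assert (sf2["s2"] / sf2["s0"]) / (sf["s2"] / sf["s0"]) == pytest.approx(3.0)
        assert sf2["s1"] / sf2["s0"] == pytest.approx(sf["s1"] / sf["s0"])

    def test_zero_reference_feature_excluded_then_empty_is_error(self):
        cm = _cm([[0, 10]], ["a", "b"])
        with pytest.raises(ValueError):
            D.reference_size_factors(cm, {"g0"})


class TestNbDifferential:
    def test_low_mean_features_removed(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(100, size=(20, 6))
        counts[0] = [8, 8, 8, 8, 8, 8]    # mean 8 < 10: dropped
        counts[1] = [10, 10, 10, 10, 10, 10]  # mean exactly 10: kept
        cm = _cm(counts, ["a"] * 3 + ["b"] * 3)
        res = D.nb_differential(cm, pd.Series(1.0, index=cm.sample_ids))
        assert "g0" not in res.index and "g1" in res.index

    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(5)
        disp, mean = 0.05, 100.0
        a = rng.negative_binomial(1 / disp, 1 / (1 + disp * mean), size=(500, 3))
        b = rng.negative_binomial(1 / disp, 1 / (1 + disp * mean / 4), size=(500, 3))
        cm = _cm(np.hstack([a, b]), ["ctrl"] * 3 + ["kd"] * 3)
        res = D.nb_differential(cm, pd.Series(1.0, index=cm.sample_ids),
                                condition_ref="ctrl")
        assert res["logFC"].mean() == pytest.approx(-2.0, abs=0.3)

    def test_single_condition_rejected(self):
        cm = _cm([[1, 2, 3]], ["a", "a", "a"])
        with pytest.raises(ValueError):
            D.nb_differential(cm, pd.Series(1.0, index=cm.sample_ids))

    def test_replicate_covariate_supported(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(100, size=(50, 4))
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(50)],
                          columns=["s0", "s1", "s2", "s3"])
        meta = pd.DataFrame({"condition": ["a", "a", "b", "b"],
                             "replicate": ["1", "2", "1", "2"]}, index=df.columns)
        cm = CountMatrix(df, meta)
        res = D.nb_differential(cm, pd.Series(1.0, index=df.columns),
                                include_replicate=True)
        assert len(res) == 50


class TestZldCall:
    @pytest.mark.parametrize("lfc,fdr,expected", [
        (-1.5, 0.001, True),
        (-0.5, 0.001, False),
        (-1.5, 0.02, False),
        (-1.0, 0.001, False),   # strict <
        (-1.5, 0.01, False),    # strict <
    ])
    def test_strict_thresholds(self, lfc, fdr, expected):
        diff = pd.DataFrame({"logFC": [lfc], "p": [fdr], "fdr": [fdr], "mean": [100]},
                            index=["t1"])
        assert ("t1" in D.call_zld_dependent(diff)) is expected


@pytest.fixture
def overlap_build():
    return GenomeBuild((("chr1", 50_000),))


class TestTranscriptCounts:
    def _tdf(self, *units):
        return transcripts_frame([TranscriptUnit(*u) for u in units])

    def test_fragment_overlapping_two_isoforms_counted_twice(self, overlap_build):
        tdf = self._tdf(("t1", "g1", "chr1", "+", 1000, 2000),
                        ("t2", "g1", "chr1", "+", 1500, 3000))
        frags = make_fragments(overlap_build, [("chr1", 1600, 1700, "+")] * 20)
        cm, _ = D.transcript_counts_fpkm(frags, tdf)
        assert cm.counts.loc["t1"].sum() == 20
        assert cm.counts.loc["t2"].sum() == 20

    def test_short_transcript_dropped(self, overlap_build):
        tdf = self._tdf(("t1", "g1", "chr1", "+", 1000, 1124),   # span 124
                        ("t2", "g1", "chr1", "+", 2000, 2125))   # span 125
        frags = make_fragments(overlap_build, [("chr1", 1000, 1100, "+")] * 20
                               + [("chr1", 2000, 2100, "+")] * 20)
        cm, _ = D.transcript_counts_fpkm(frags, tdf)
        assert list(cm.counts.index) == ["t2"]

    def test_min_sum_is_strict(self, overlap_build):
        tdf = self._tdf(("t1", "g1", "chr1", "+", 1000, 2000),
                        ("t2", "g1", "chr1", "+", 10_000, 11_000))
        frags = make_fragments(
            overlap_build,
            [("chr1", 1100, 1200, "+")] * 10 + [("chr1", 10_100, 10_200, "+")] * 11)
        cm, _ = D.transcript_counts_fpkm(frags, tdf)
        assert "t1" not in cm.counts.index  # total exactly 10: dropped
        assert "t2" in cm.counts.index

    def test_fpkm_invariant_under_duplication(self, overlap_build):
        tdf = self._tdf(("t1", "g1", "chr1", "+", 1000, 2000),
                        ("t2", "g1", "chr1", "+", 5000, 9000))
        rows = [("chr1", 1100, 1200, "+")] * 30 + [("chr1", 6000, 6100, "-")] * 50
        one = make_fragments(overlap_build, rows)
        two = make_fragments(overlap_build, rows + rows)
        _, fpkm1 = D.transcript_counts_fpkm(one, tdf)
        _, fpkm2 = D.transcript_counts_fpkm(two, tdf)
        pd.testing.assert_frame_equal(fpkm1, fpkm2)

    def test_stranded_mode_filters(self, overlap_build):
        tdf = self._tdf(("t1", "g1", "chr1", "+", 1000, 2000))
        frags = make_fragments(overlap_build, [("chr1", 1100, 1200, "+")] * 20
                               + [("chr1", 1100, 1200, "-")] * 20)
        cm_un, _ = D.transcript_counts_fpkm(frags, tdf)
        cm_st, _ = D.transcript_counts_fpkm(frags, tdf, stranded=True)
        assert cm_un.counts.loc["t1"].sum() == 40
        assert cm_st.counts.loc["t1"].sum() == 20


class TestRelacs:
    def test_no_change_gives_unity(self):
        f = D.relacs_double_ratio(100, 100, 50, 50, 1000, 1000, 500, 500)
        assert f == pytest.approx(1.0)

    def test_depth_change_cancels(self):
        base = D.relacs_double_ratio(50, 100, 50, 50, 1000, 1000, 500, 500)
        deeper = D.relacs_double_ratio(100, 100, 50, 50, 2000, 1000, 500, 500)
        assert deeper == pytest.approx(base)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            D.relacs_double_ratio(10, 0, 5, 5, 100, 100, 50, 50)


class TestSpikein:
    def test_equal_spike_counts_unit_factors(self):
        sf = D.spikein_size_factors(pd.Series({"s1": 500, "s2": 500}))
        assert sf.tolist() == pytest.approx([1.0, 1.0])

    def test_double_spike_halves_factor(self):
        sf = D.spikein_size_factors(pd.Series({"s1": 500, "s2": 1000}))
        assert sf["s2"] / sf["s1"] == pytest.approx(0.5)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0)

    def test_zero_spike_rejected(self):
        with pytest.raises(ValueError, match="zero spike"):
            D.spikein_size_factors(pd.Series({"s1": 500, "s2": 0}))


class TestStabilizedLog:
    def test_closed_forms(self):
        cm = _cm([[0, 7]], ["a", "b"])
        out = D.stabilized_log(cm, pd.Series(1.0, index=cm.sample_ids))
        assert out.iloc[0].tolist() == pytest.approx([0.0, 3.0])

    def test_replicate_mean(self):
        cm = _cm([[3, 5, 10]], ["a", "a", "b"])
        logs = pd.DataFrame([[3.0, 5.0, 10.0]], index=["g0"], columns=cm.sample_ids)
        out = D.replicate_mean(logs, cm.meta)
        assert out.loc["g0", "a"] == pytest.approx(4.0)
        assert out.loc["g0", "b"] == pytest.approx(10.0)


class TestBinCounts:
    def test_mean_boundary_and_midpoint_assignment(self, overlap_build):
        # 25 fragments in one bin (mean exactly 25: dropped), 26 in another (kept);
        # a fragment spanning two bins lands in its midpoint's bin
        rows = ([("chr1", 1000, 1100, "+")] * 25
                + [("chr1", 2000, 2100, "+")] * 26
                + [("chr1", 2480, 2520, "+")])   # midpoint 2500 -> bin 5
        frags = make_fragments(overlap_build, rows)
        cm = D.bin_counts(frags, bin_size=500, min_mean=25)
        assert "chr1:1000-1500" not in cm.counts.index
        assert cm.counts.loc["chr1:2000-2500"].iloc[0] == 26
        assert "chr1:2500-3000" not in cm.counts.index  # single fragment, mean 1
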