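import numpy as np
import pandas as pd
import pytest

from zga import insulation as I
from zga.genome import ContactMatrix, GenomeBuild


def _sym(rng, n, lam=20.0):
    a = np.triu(rng.poisson(lam, size=(n, n)).astype(float))
    return a + np.triu(a, 1).T


def brute_force_insulation(balanced, w_list):
    """Independent diamond-mean oracle (plain loops)."""
    n = balanced.shape[0]
    w_max = max(w_list)
    tracks = []
    for w in w_list:
        t = np.full(n, np.nan)
        for i in range(w, n - w):
            block = balanced[i - w:i, i + 1:i + w + 1]
            vals = block[np.isfinite(block)]
            if len(vals):
                t[i] = vals.mean()
        mean = np.nanmean(t)
        tracks.append(np.log2(t / mean))
    score = np.vstack(tracks).mean(axis=0)
    score[:w_max] = np.nan
    score[n - w_max:] = np.nan
    return score


class TestBinContacts:
    def test_pair_assignment(self):
        build = GenomeBuild((("chr1", 20_000),))
        pairs = pd.DataFrame({"chrom1": ["chr1"], "pos1": [1000],
                              "chrom2": ["chr1"], "pos2": [5000]})
        m = I.bin_contacts(pairs, build, bin_size=2000)["chr1"]
        assert m.matrix[0, 2] == 1 and m.matrix[2, 0] == 1

    def test_inter_chromosomal_discarded(self):
        build = GenomeBuild((("chr1", 20_000), ("chr2", 20_000)))
        pairs = pd.DataFrame({"chrom1": ["chr1"], "pos1": [1000],
                              "chrom2": ["chr2"], "pos2": [5000]})
        mats = I.bin_contacts(pairs, build, bin_size=2000)
        assert mats["chr1"].matrix.sum() == 0 and mats["chr2"].matrix.sum() == 0

    def test_empty_input_zero_matrix(self):
        build = GenomeBuild((("chr1", 20_000),))
        pairs = pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2"])
        assert I.bin_contacts(pairs, build, bin_size=2000)["chr1"].matrix.sum() == 0


class TestBalance:
    def test_already_balanced_matrix_keeps_unit_weights(self):
        n = 6
        m = ContactMatrix("chr1", 1000, np.ones((n, n)))
        w = I.balance(m)
        assert np.nanstd(w) / np.nanmean(w) < 1e-4

    def test_heavy_row_corrected(self):
        rng = np.random.default_rng(0)
        mat = _sym(rng, 30)
        mat[3, :] *= 10
        mat[:, 3] = mat[3, :]
        m = ContactMatrix("chr1", 1000, mat)
        I.balance(m)
        s = np.nansum(m.balanced(), axis=1)
        mask = np.isfinite(m.weights)
        assert s[mask].std() / s[mask].mean() < 1e-4

    def test_zero_row_masked(self):
        rng = np.random.default_rng(1)
        mat = _sym(rng, 10)
        mat[4, :] = 0.0
        mat[:, 4] = 0.0
        m = ContactMatrix("chr1", 1000, mat)
        w = I.balance(m)
        assert np.isnan(w[4])
        track = I.insulation_score(m, min_depth=2000, max_depth=3000, step=1000)
        assert not track.loc[4, "covered"]


class TestInsulationScore:
    def test_uniform_matrix_scores_zero(self):
        m = ContactMatrix("chr1", 1000, np.ones((40, 40)))
        I.balance(m)
        track = I.insulation_score(m, min_depth=3000, max_depth=8000, step=1000)
        covered = track[track["covered"]]
        assert np.allclose(covered["score"], 0.0, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for n in (30, 60):
            m = ContactMatrix("chr1", 1000, _sym(rng, n))
            I.balance(m)
            w_list = [3, 4, 5]
            track = I.insulation_score(m, min_depth=3000, max_depth=5000, step=1000)
            oracle = brute_force_insulation(m.balanced(), w_list)
            got = track["score"].to_numpy()
            both = np.isfinite(oracle) & np.isfinite(got)
            np.testing.assert_allclose(got[both], oracle[both], rtol=1e-10)
            assert (np.isfinite(got) == np.isfinite(oracle)).all()

    def test_two_blocks_minimum_at_junction(self):
        n, b = 40, 20
        mat = np.zeros((n, n))
        mat[:b, :b] = 10.0
        mat[b:, b:] = 10.0
        mat += np.eye(n)  # keep marginals nonzero without linking the blocks
        m = ContactMatrix("chr1", 1000, mat)
        I.balance(m)
        track = I.insulation_score(m, min_depth=3000, max_depth=5000, step=1000)
        s = track["score"].to_numpy()
        # the two crossing-free diamonds straddle the junction; the
        # leftmost tie-break lands on the last bin of the left block
        assert np.nanargmin(s) == b - 1
        assert np.isneginf(s[b - 1]) and np.isneginf(s[b])

    def test_short_chromosome_uncovered(self):
        m = ContactMatrix("chr1", 1000, np.ones((8, 8)))
        I.balance(m)
        track = I.insulation_score(m, min_depth=4000, max_depth=6000, step=1000)
        assert not track["covered"].any()


class TestBoundaries:
    def _track(self, scores):
        n = len(scores)
        return pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 1000,
                             "end": (np.arange(n) + 1) * 1000,
                             "score": scores, "covered": np.isfinite(scores)})

    def test_single_minimum_with_prominence(self):
        s = np.array([0.0, 0.5, -0.3, 0.4, 0.1, np.nan])
        out = I.call_boundaries(self._track(s), delta=0.01)
        assert out["bin"].tolist() == [2]
        assert out.iloc[0]["prominence"] == pytest.approx(0.7)

    def test_monotone_track_has_no_boundary(self):
        s = np.linspace(1.0, -1.0, 20)
        assert len(I.call_boundaries(self._track(s))) == 0

    def test_shallow_minimum_filtered_by_delta(self):
        s = np.array([0.0, 0.5, -0.3, 0.4, 0.397, 0.4, 0.398, 0.5, 0.0])
        out = I.call_boundaries(self._track(s), delta=0.01)
        assert out["bin"].tolist() == [2]   # the 0.003-prominence dip is dropped

    def test_boundary_needs_flanking_maxima(self):
        s = np.array([-1.0, -0.5, 0.0, -0.5, -1.0])  # minima at edges don't count
        assert len(I.call_boundaries(self._track(s))) == 0


class TestProfilesAndDistance:
    def _track(self, scores, chrom="chr1"):
        n = len(scores)
        return pd.DataFrame({"chrom": chrom, "start": np.arange(n) * 1000,
                             "end": (np.arange(n) + 1) * 1000,
                             "score": scores, "covered": np.isfinite(scores)})

    def test_single_tss_profile_is_own_window(self):
        s = np.arange(20, dtype=float)
        tss = pd.DataFrame({"chrom": ["chr1"], "tss": [10_500], "strand": ["+"]})
        prof = I.profile_over_groups(self._track(s), {"g": tss}, flank=3000)["g"]
        assert prof["median"].tolist() == [7, 8, 9, 10, 11, 12, 13]
        assert prof["se"].isna().all()  # a single member has no spread estimate

    def test_strand_flip_mirrors_profile(self):
        s = np.arange(20, dtype=float)
        plus = pd.DataFrame({"chrom": ["chr1"], "tss": [10_500], "strand": ["+"]})
        minus = pd.DataFrame({"chrom": ["chr1"], "tss": [10_500], "strand": ["-"]})
        out = I.profile_over_groups(self._track(s), {"p": plus, "m": minus}, flank=3000)
        np.testing.assert_array_equal(out["p"]["median"].to_numpy(),
                                      out["m"]["median"].to_numpy()[::-1])

    def test_identical_members_have_zero_se(self):
        s = np.sin(np.arange(40) / 3.0)
        tss = pd.DataFrame({"chrom": ["chr1"] * 2, "tss": [10_500, 10_500],
                            "strand": ["+", "+"]})
        prof = I.profile_over_groups(self._track(s), {"g": tss}, flank=3000)["g"]
        assert (prof["se"] == 0).all()

    def test_boundary_distance(self):
        bounds = pd.DataFrame({"chrom": ["chr1"], "bin": [10], "score": [-1.0],
                               "prominence": [1.0]})
        tss = pd.DataFrame({"chrom": ["chr1", "chr1", "chr2"],
                            "tss": [10_500, 14_500, 3_000]})
        d = I.boundary_distance(tss, bounds, bin_size=1000)
        assert d.iloc[0] == 0.0
        assert d.iloc[1] == pytest.approx(4000.0)
        assert np.isnan(d.iloc[2])   # no boundary on that chromosome


class TestDifference:
    def _track(self, scores):
        n = len(scores)
        return pd.DataFrame({"chrom": "chr1", "start": np.arange(n) * 1000,
                             "end": (np.arange(n) + 1) * 1000,
                             "score": scores, "covered": np.isfinite(scores)})

    def test_equal_tracks_zero(self):
        a = self._track(np.array([0.1, 0.2, 0.3]))
        out = I.insulation_difference(a, a.copy())
        assert np.allclose(out["score"], 0.0)

    def test_uncovered_propagates(self):
        a = self._track(np.array([0.1, 0.2, 0.3]))
        b = self._track(np.array([0.1, np.nan, 0.3]))
        out = I.insulation_difference(a, b)
        assert np.isnan(out.loc[1, "score"]) and not out.loc[1, "covered"]

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = self._track(rng.normal(size=10))
        b = self._track(rng.normal(size=10))
        ab = I.insulation_difference(a, b)["score"].to_numpy()
        ba = I.insulation_difference(b, a)["score"].to_numpy()
        np.testing.assert_allclose(ab, -ba)
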