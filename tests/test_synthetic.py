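import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zga.synthetic import (
    SimConfig,
    planted_boundaries,
    simulate_chip,
    simulate_contacts,
    simulate_groseq,
    simulate_proteomics,
    simulate_rnaseq_counts,
    simulate_truth_genome,
)


class TestTruthGenome:
    def test_exact_class_counts(self, default_truth, default_config):
        _, _, truth = default_truth
        cfg = default_config
        n_active = int(truth["active"].sum())
        assert n_active == round(cfg.frac_active * cfg.n_genes)
        assert truth["zld_dependent"].sum() == round(cfg.frac_zld_of_active * n_active)
        assert (truth["truth_class"] == "h2az_pos").sum() == round(
            cfg.frac_h2az_pos_of_active * n_active)

    def test_seed_contract(self):
        cfg = SimConfig(seed=5, n_genes=60, chrom_length=500_000)
        a = simulate_truth_genome(cfg)[2]
        b = simulate_truth_genome(cfg)[2]
        pd.testing.assert_frame_equal(a, b)

    def test_h2az_fraction_in_binomial_interval(self):
        cfg = SimConfig(seed=3, frac_h2az_pos_of_active=0.65)
        _, _, truth = simulate_truth_genome(cfg)
        n_active = truth["active"].sum()
        k = (truth["truth_class"] == "h2az_pos").sum()
        lo, hi = stats.binom.interval(0.99, n_active, 0.65)
        assert lo <= k <= hi

    def test_min_spacing_respected(self, default_truth, default_config):
        _, _, truth = default_truth
        for _, sub in truth.groupby("chrom"):
            gaps = np.diff(np.sort(sub["tss"].to_numpy()))
            assert (gaps >= default_config.min_tss_spacing).all()

    def test_too_small_genome_raises(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_truth_genome(SimConfig(n_genes=400, chrom_length=300_000))

    def test_zld_implies_active(self, default_truth):
        _, _, truth = default_truth
        assert (truth["active"] | ~truth["zld_dependent"]).all()


class TestGroseq:
    def test_inactive_tss_sees_background_only(self, default_truth, default_config):
        build, _, truth = default_truth
        frags = simulate_groseq(truth, default_config, build, "Ctrl")
        frame = frags.frame
        inactive = truth[~truth["active"]]
        n_near = 0
        for r in inactive.head(50).itertuples():
            sel = (frame["chrom"] == r.chrom) & (frame["start"] >= r.tss - 200) & (
                frame["start"] < r.tss + 200)
            n_near += int(sel.sum())
        # Poisson background: 2 strands x rate x width x reps per promoter
        lam = (2 * default_config.groseq_background_per_bp * 400
               * default_config.groseq_reps)
        lo, hi = stats.poisson.interval(0.9999, lam * 50)
        assert lo <= n_near <= hi

    def test_replicates_share_generative_law(self, default_truth, default_config):
        build, _, truth = default_truth
        frags = simulate_groseq(truth, default_config, build, "Ctrl")
        sizes = frags.frame.groupby("replicate").size()
        assert len(sizes) == default_config.groseq_reps
        assert sizes.max() / sizes.min() < 1.05

    def test_single_active_gene_no_background(self):
        cfg = SimConfig(seed=2, n_genes=4, chrom_length=500_000, n_chromosomes=1,
                        frac_active=0.25, frac_zld_of_active=0, frac_h2az_pos_of_active=0,
                        frac_minus1_of_h2az_neg=0, groseq_background_per_bp=0.0)
        build, _, truth = simulate_truth_genome(cfg)
        frags = simulate_groseq(truth, cfg, build, "Ctrl")
        gene = truth[truth["active"]].iloc[0]
        assert (frags.frame["strand"] == gene["strand"]).all()
        assert frags.frame["start"].between(gene["tss"] - 2000, gene["tss"] + 2000).all()


class TestChip:
    def test_unknown_assay(self, default_truth, default_config):
        build, _, truth = default_truth
        with pytest.raises(ValueError, match="unknown assay"):
            simulate_chip(truth, default_config, build, "H3K27ac")

    def test_depletion_ratio_over_planted_dyads(self, default_truth, default_config):
        build, _, truth = default_truth
        ctrl = simulate_chip(truth, default_config, build, "H2A.Z", "Ctrl")
        kd = simulate_chip(truth, default_config, build, "H2A.Z", "DomKD")

        def planted_count(fs):
            n = 0
            frame = fs.frame
            for r in truth[truth["h2az_plus1"].notna()].itertuples():
                sign = 1 if r.strand == "+" else -1
                dyad = r.tss + sign * int(r.h2az_plus1)
                mids = (frame["start"] + frame["end"]) // 2
                n += int(((frame["chrom"] == r.chrom)
                          & (mids - dyad).abs().le(80)).sum())
            return n

        ratio = planted_count(kd) / planted_count(ctrl)
        assert ratio == pytest.approx(default_config.depletion_factor, abs=0.05)

    def test_mnase_lengths_span_configured_range(self, default_truth, default_config):
        build, _, truth = default_truth
        mn = simulate_chip(truth, default_config, build, "MNase", "Ctrl")
        lengths = mn.lengths
        lo, hi = default_config.mnase_frag_len_range
        assert lengths.min() >= lo and lengths.max() <= hi
        assert (lengths < 130).any() and (lengths > 200).any()

    def test_input_is_unstructured(self, default_truth, default_config):
        build, _, truth = default_truth
        inp = simulate_chip(truth, default_config, build, "input", "Ctrl")
        frame = inp.frame[inp.frame["chrom"] == "chr1"]
        counts, _ = np.histogram(frame["start"], bins=50)
        # uniform rate: no bin should deviate grossly from the mean
        assert counts.std() / counts.mean() < 0.1

    def test_spike_share_matches_config(self, default_truth, default_config):
        build, _, truth = default_truth
        chip = simulate_chip(truth, default_config, build, "H2A.Z", "Ctrl")
        for _, sub in chip.frame.groupby("replicate"):
            share = (sub["chrom"] == "spike").mean()
            n = len(sub)
            se = np.sqrt(0.05 * 0.95 / n)
            assert abs(share - default_config.spike_fraction) < 5 * se

    def test_seed_determinism(self, default_truth, default_config):
        build, _, truth = default_truth
        a = simulate_chip(truth, default_config, build, "H2A.Z", "Ctrl")
        b = simulate_chip(truth, default_config, build, "H2A.Z", "Ctrl")
        pd.testing.assert_frame_equal(a.frame, b.frame)


class TestRnaseq:
    def test_maternal_genes_dominate_unfertilized(self, default_truth, default_config):
        _, _, truth = default_truth
        cm = simulate_rnaseq_counts(truth, default_config, "unfertilized")
        mat = cm.counts[truth["maternal"].to_numpy()]
        non = cm.counts[~truth["maternal"].to_numpy()]
        assert mat.mean().mean() > 100 * max(non.mean().mean(), 0.01)

    def test_unknown_kind(self, default_truth, default_config):
        _, _, truth = default_truth
        with pytest.raises(ValueError):
            simulate_rnaseq_counts(truth, default_config, "larva")


class TestContacts:
    def test_symmetry_exact(self, default_truth, default_config):
        build, _, truth = default_truth
        mats, _ = simulate_contacts(truth, default_config, build)
        for m in mats.values():
            np.testing.assert_array_equal(m.matrix, m.matrix.T)

    def test_no_boundaries_when_attenuation_one(self, default_truth):
        build, _, truth = default_truth
        cfg = SimConfig(seed=1, boundary_attenuation=1.0)
        mats, bounds = simulate_contacts(truth, cfg, build)
        m = mats["chr1"].matrix
        # distance-decay only: average counts at fixed distance are flat
        d20 = np.diagonal(m, offset=20)
        half = len(d20) // 2
        assert abs(d20[:half].mean() - d20[half:].mean()) < 0.2 * d20.mean()

    def test_boundaries_respect_separation(self, default_truth, default_config):
        build, _, truth = default_truth
        bounds = planted_boundaries(truth, default_config, build)
        for bs in bounds.values():
            if len(bs) > 1:
                assert np.diff(bs).min() >= default_config.boundary_min_sep_bins


class TestProteomics:
    def test_flagged_rows_present(self, default_config):
        table = simulate_proteomics(default_config)
        assert table["contaminant"].sum() == default_config.prot_n_contaminants
        assert table["decoy"].sum() == default_config.prot_n_decoys
        assert table["site_only"].sum() == default_config.prot_n_site_only

    def test_missingness_is_left_censored(self, default_config):
        table = simulate_proteomics(default_config)
        samples = list(table.attrs["groups"])
        vals = table[samples]
        observed = vals.stack()
        # censoring removes the low tail: observed minimum above what a
        # complete normal sample of this size would show
        assert observed.min() > default_config.prot_base_mean - 5 * default_config.prot_base_sd
        assert vals.isna().to_numpy().mean() > 0.05

    def test_seed_determinism(self, default_config):
        pd.testing.assert_frame_equal(
            simulate_proteomics(default_config), simulate_proteomics(default_config))
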