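"""Synthetic embryo-genomics data with planted ground truth.

The generator emulates the data types of a zygotic-genome-activation
study in *Drosophila*: strand-specific nascent transcription at a
designated active-promoter subset, nucleosome-phased H2A.Z / MNase
fragments with a knockdown depletion factor and a spike-in contig,
distance-decay Hi-C contact matrices with planted TAD boundaries,
maternal RNA counts, and a two-group label-free-quantification protein
table with missing-not-at-random dropout.

Every assay draws from its own RNG stream derived from the master seed,
so adding one assay never perturbs another's data.  Identical
configuration (including seed) gives identical output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome import ContactMatrix, CountMatrix, FragmentSet, GenomeBuild, TranscriptUnit

TRUTH_COLUMNS = [
    "gene_id", "chrom", "strand", "tss", "length", "active", "zld_dependent",
    "h2az_plus1", "h2az_minus1", "maternal", "planted_logFC_kd",
    "boundary_near_tss", "truth_class",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic embryo.

    Defaults describe a toy genome of 2 chromosomes x 1 Mb with 400
    genes and a ~48 kb spike-in contig, sized so that a full run takes
    minutes on one CPU while every downstream rule has enough signal to
    be recovered.
    """

    seed: int = 0

    # genome
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    spike_contig: str = "spike"
    spike_length: int = 48_000
    n_genes: int = 400
    min_tss_spacing: int = 3_000
    edge_margin: int = 110_000       # keeps TSS insulation windows covered
    gene_length_range: tuple[int, int] = (800, 1_500)

    # class fractions
    frac_active: float = 0.6
    frac_zld_of_active: float = 0.10
    frac_h2az_pos_of_active: float = 0.62
    frac_minus1_of_h2az_neg: float = 0.26
    frac_maternal: float = 0.40

    # planted chromatin geometry (strand-aware signed offsets, bp)
    plus1_offset: int = 120
    minus1_offset: int = -180
    phasing_sd: float = 20.0

    # planted knockdown effects (log2)
    lfc_kd_h2az_pos: float = -1.5
    lfc_kd_minus1: float = -0.6
    zld_effect_lfc: float = -2.0     # Pol II drop at Zld-dependent genes in ZldKD

    # nascent transcription
    groseq_reps: int = 3
    groseq_frags_per_gene: float = 600.0
    groseq_decay_bp: float = 300.0
    groseq_frag_len: int = 60
    groseq_background_per_bp: float = 0.005   # per strand, per replicate

    # chromatin profiling
    chip_reps: int = 2
    chip_frags_per_nucleosome: float = 35.0
    h2az_dispersed_per_bp: float = 0.07       # non-promoter H2A.Z, not depleted
    dispersed_exclusion_bp: int = 1_000       # dispersed signal keeps clear of TSSs
    chip_background_per_bp: float = 0.0005
    nucleosome_frag_len: int = 147
    mnase_frag_len_range: tuple[int, int] = (100, 220)
    depletion_factor: float = 0.5             # H2A.Z rate multiplier in DomKD
    spike_fraction: float = 0.05
    polii_frags_per_gene: float = 2500.0
    polii_frag_len: int = 150
    input_frags_per_bp: float = 0.05

    # RNA counts
    rnaseq_unfert_reps: int = 4
    rnaseq_embryo_reps: int = 3
    rna_maternal_rate: float = 50.0           # reads per kb at depth 1
    rna_active_rate: float = 20.0
    rna_background_rate: float = 0.05
    rna_dispersion: float = 0.05

    # contacts
    hic_bin_size: int = 2_000
    contact_scale: float = 3_000.0            # expected counts at distance 1 bin
    contact_decay: float = 1.0
    boundary_attenuation: float = 0.2
    boundary_min_sep_bins: int = 30
    boundary_edge_margin_bins: int = 120      # no boundaries near chromosome ends
    boundary_weakening_kd: float = 0.5        # KD attenuation = att ** weakening

    # proteomics
    prot_n: int = 1_000
    prot_reps: int = 3
    prot_frac_enriched: float = 0.05
    prot_log2fc: float = 2.0
    prot_sd: float = 0.3
    prot_base_mean: float = 25.0
    prot_base_sd: float = 2.0
    prot_censor_quantile: float = 0.12
    prot_n_contaminants: int = 20
    prot_n_decoys: int = 20
    prot_n_site_only: int = 10

    def __post_init__(self) -> None:
        if self.frac_active > 1 or self.frac_active < 0:
            raise ValueError("frac_active outside [0, 1]")
        if not 0 < self.depletion_factor <= 1:
            raise ValueError("depletion_factor must be in (0, 1]")
        for name in ("groseq_frags_per_gene", "chip_frags_per_nucleosome",
                     "polii_frags_per_gene", "contact_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Named RNG stream deterministically derived from the master seed."""
        tag = zlib.crc32(stream.encode())
        return np.random.default_rng(np.random.SeedSequence([self.seed, tag]))

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def _build(config: SimConfig) -> GenomeBuild:
    chroms = [(f"chr{i + 1}", config.chrom_length) for i in range(config.n_chromosomes)]
    chroms.append((config.spike_contig, config.spike_length))
    return GenomeBuild(tuple(chroms), frozenset({config.spike_contig}))


def _round_pick(rng, candidates: np.ndarray, fraction: float) -> np.ndarray:
    """Pick round(fraction * n) members of ``candidates`` without replacement."""
    k = int(round(fraction * len(candidates)))
    return rng.choice(candidates, size=k, replace=False)


def simulate_truth_genome(
    config: SimConfig,
) -> tuple[GenomeBuild, list[TranscriptUnit], pd.DataFrame]:
    """Place genes and draw planted class labels.

    Genes are placed on a jittered grid so pairwise TSS distances stay
    above ``min_tss_spacing`` (promoters never collide) and away from
    chromosome edges so every TSS has full Hi-C window coverage.
    Class counts follow the configured fractions with deterministic
    rounding; membership is drawn at random.
    """
    rng = config.rng("truth")
    build = _build(config)
    per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per_chrom[: config.n_genes % config.n_chromosomes] += 1

    usable = config.chrom_length - 2 * config.edge_margin
    rows = []
    gid = 0
    for ci, n_here in enumerate(per_chrom):
        if n_here == 0:
            continue
        spacing = usable / n_here
        if spacing < config.min_tss_spacing:
            raise ValueError(
                f"genome too small: grid spacing {spacing:.0f} bp < "
                f"min_tss_spacing {config.min_tss_spacing}"
            )
        jitter_half = (spacing - config.min_tss_spacing) / 2.0
        grid = config.edge_margin + spacing * (np.arange(n_here) + 0.5)
        tss = (grid + rng.uniform(-jitter_half, jitter_half, size=n_here)).astype(int)
        strands = rng.choice(["+", "-"], size=n_here)
        lengths = rng.integers(*config.gene_length_range, size=n_here, endpoint=True)
        for t, s, ln in zip(tss, strands, lengths):
            rows.append((f"gene{gid:04d}", f"chr{ci + 1}", s, int(t), int(ln)))
            gid += 1

    truth = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "length"])
    n = len(truth)
    idx = np.arange(n)

    active_idx = np.sort(_round_pick(rng, idx, config.frac_active))
    truth["active"] = False
    truth.loc[active_idx, "active"] = True

    zld_idx = np.sort(_round_pick(rng, active_idx, config.frac_zld_of_active))
    truth["zld_dependent"] = False
    truth.loc[zld_idx, "zld_dependent"] = True

    independent = np.setdiff1d(active_idx, zld_idx)
    n_pos = int(round(config.frac_h2az_pos_of_active * len(active_idx)))
    if n_pos > len(independent):
        raise ValueError("frac_h2az_pos_of_active exceeds the Zld-independent set")
    pos_idx = np.sort(rng.choice(independent, size=n_pos, replace=False))
    neg_idx = np.setdiff1d(independent, pos_idx)
    minus1_idx = np.sort(_round_pick(rng, neg_idx, config.frac_minus1_of_h2az_neg))

    truth["h2az_plus1"] = np.nan
    truth["h2az_minus1"] = np.nan
    truth.loc[pos_idx, "h2az_plus1"] = float(config.plus1_offset)
    truth.loc[pos_idx, "h2az_minus1"] = float(config.minus1_offset)
    truth.loc[minus1_idx, "h2az_minus1"] = float(config.minus1_offset)

    maternal_idx = np.sort(_round_pick(rng, idx, config.frac_maternal))
    truth["maternal"] = False
    truth.loc[maternal_idx, "maternal"] = True

    lfc = np.zeros(n)
    lfc[pos_idx] = config.lfc_kd_h2az_pos
    lfc[minus1_idx] = config.lfc_kd_minus1
    truth["planted_logFC_kd"] = lfc

    # TAD boundaries are planted at Zld-dependent TSSs, thinned to the
    # configured separation and kept clear of chromosome ends so every
    # boundary has full insulation-window coverage; the flag marks
    # exactly the genes whose boundary is actually planted.
    boundary_flag = np.zeros(n, dtype=bool)
    bin_size = config.hic_bin_size
    n_bins = config.chrom_length // bin_size
    for chrom in truth["chrom"].unique():
        zsel = truth.index[(truth["chrom"] == chrom) & truth["zld_dependent"]]
        order = truth.loc[zsel, "tss"].sort_values().index
        last_bin = None
        for gi in order:
            b = int(truth.loc[gi, "tss"]) // bin_size
            if b < config.boundary_edge_margin_bins or b > n_bins - config.boundary_edge_margin_bins:
                continue
            if last_bin is not None and b - last_bin < config.boundary_min_sep_bins:
                continue
            boundary_flag[gi] = True
            last_bin = b
    truth["boundary_near_tss"] = boundary_flag

    cls = np.full(n, "inactive", dtype=object)
    cls[active_idx] = "h2az_neg_none"
    cls[zld_idx] = "zld_dep"
    cls[pos_idx] = "h2az_pos"
    cls[minus1_idx] = "h2az_neg_minus1"
    truth["truth_class"] = cls

    transcripts = []
    for r in truth.itertuples(index=False):
        if r.strand == "+":
            start, end = r.tss, min(r.tss + r.length, config.chrom_length)
        else:
            start, end = max(r.tss + 1 - r.length, 0), r.tss + 1
        transcripts.append(
            TranscriptUnit(f"{r.gene_id}.t1", r.gene_id, r.chrom, r.strand, start, end)
        )
    return build, transcripts, truth.set_index("gene_id")


def _clip_fragments(starts, lengths, chrom_len):
    starts = np.clip(starts, 0, chrom_len - 1)
    ends = np.clip(starts + lengths, 1, chrom_len)
    starts = np.minimum(starts, ends - 1)
    return starts, ends


def _frame(chroms, starts, ends, strands, assay, condition, replicate):
    return pd.DataFrame(
        {
            "chrom": chroms,
            "start": starts.astype(int),
            "end": ends.astype(int),
            "strand": strands,
            "assay": assay,
            "condition": condition,
            "replicate": str(replicate),
        }
    )


def _uniform_background(rng, build, rate_per_bp, frag_len, assay, condition, rep,
                        chrom_subset=None):
    frames = []
    names = chrom_subset if chrom_subset is not None else build.main_chromosomes
    for chrom in names:
        L = build.lengths[chrom]
        n = rng.poisson(rate_per_bp * L)
        if n == 0:
            continue
        starts = rng.integers(0, L - frag_len, size=n)
        strands = rng.choice(["+", "-"], size=n)
        frames.append(_frame(np.repeat(chrom, n), starts, starts + frag_len,
                             strands, assay, condition, rep))
    return frames


def simulate_groseq(
    truth: pd.DataFrame,
    config: SimConfig,
    build: GenomeBuild,
    condition: str = "Ctrl",
) -> FragmentSet:
    """Nascent-transcription fragments.

    Active promoters emit sense-strand fragments whose 5' ends fall at
    an exponentially decaying distance downstream of the TSS, over a
    uniform Poisson background on both strands.  In the knockdown
    condition each gene's emission rate is scaled by its planted log2
    fold change.
    """
    rng = config.rng(f"groseq_{condition}")
    frames = []
    for rep in range(1, config.groseq_reps + 1):
        for r in truth.itertuples():
            if not r.active:
                continue
            rate = config.groseq_frags_per_gene
            if condition != "Ctrl":
                rate *= 2.0 ** r.planted_logFC_kd
            n = rng.poisson(rate)
            if n == 0:
                continue
            offsets = rng.exponential(config.groseq_decay_bp, size=n)
            offsets = np.minimum(offsets, max(r.length - config.groseq_frag_len, 1)).astype(int)
            if r.strand == "+":
                starts = r.tss + offsets
            else:
                starts = r.tss - offsets - (config.groseq_frag_len - 1)
            starts, ends = _clip_fragments(starts, config.groseq_frag_len,
                                           build.lengths[r.chrom])
            frames.append(_frame(np.repeat(r.chrom, n), starts, ends,
                                 np.repeat(r.strand, n), "groseq", condition, rep))
        frames += _uniform_background(
            rng, build, 2 * config.groseq_background_per_bp, config.groseq_frag_len,
            "groseq", condition, rep)
    return FragmentSet(pd.concat(frames, ignore_index=True), build)


def _nucleosome_positions(truth: pd.DataFrame, which: str, config: SimConfig):
    """Genomic dyad centers for planted +1 / -1 nucleosomes.

    ``which`` selects occupancy semantics: "h2az" places nucleosomes only
    where the variant is planted, "all" places +1/-1 at every gene
    (nucleosome positioning is independent of the variant).
    """
    rows = []
    for r in truth.itertuples():
        sign = 1 if r.strand == "+" else -1
        if which == "h2az":
            if np.isfinite(r.h2az_plus1):
                rows.append((r.chrom, r.tss + sign * int(r.h2az_plus1)))
            if np.isfinite(r.h2az_minus1):
                rows.append((r.chrom, r.tss + sign * int(r.h2az_minus1)))
        else:
            rows.append((r.chrom, r.tss + sign * config.plus1_offset))
            rows.append((r.chrom, r.tss + sign * config.minus1_offset))
    return rows


def _dispersed_h2az(rng, build, truth, config, condition, rep):
    """Non-promoter H2A.Z fragments (gene bodies / intergenic).

    This component dominates the IP library, is not depleted in the
    knockdown, and stays ``dispersed_exclusion_bp`` clear of every TSS so
    promoter windows are owned by the planted nucleosomes.
    """
    frames = []
    frag_len = config.nucleosome_frag_len
    excl = config.dispersed_exclusion_bp
    for chrom in build.main_chromosomes:
        L = build.lengths[chrom]
        tss = np.sort(truth.loc[truth["chrom"] == chrom, "tss"].to_numpy())
        n = rng.poisson(config.h2az_dispersed_per_bp * L)
        if n == 0:
            continue
        mids = rng.integers(0, L, size=n)
        if len(tss):
            k = np.searchsorted(tss, mids)
            d_right = np.where(k < len(tss), tss[np.minimum(k, len(tss) - 1)] - mids,
                               np.inf)
            d_left = np.where(k > 0, mids - tss[np.maximum(k - 1, 0)], np.inf)
            mids = mids[np.minimum(d_right, d_left) > excl]
        if not len(mids):
            continue
        starts = mids - frag_len // 2
        starts, ends = _clip_fragments(starts, frag_len, L)
        strands = rng.choice(["+", "-"], size=len(mids))
        frames.append(_frame(np.repeat(chrom, len(mids)), starts, ends, strands,
                             "H2A.Z", condition, rep))
    return frames


def _spike_fragments(rng, build, config, n_main, frag_len, assay, condition, rep):
    s = config.spike_fraction
    n = rng.poisson(n_main * s / (1.0 - s))
    if n == 0:
        return []
    L = build.lengths[config.spike_contig]
    starts = rng.integers(0, L - frag_len, size=n)
    strands = rng.choice(["+", "-"], size=n)
    return [_frame(np.repeat(config.spike_contig, n), starts, starts + frag_len,
                   strands, assay, condition, rep)]


def simulate_chip(
    truth: pd.DataFrame,
    config: SimConfig,
    build: GenomeBuild,
    assay: str,
    condition: str = "Ctrl",
) -> FragmentSet:
    """Chromatin-profiling fragments for one assay and condition.

    ``H2A.Z``  nucleosome-sized fragments with dyads Gaussian around the
               planted +1/-1 offsets; in "DomKD" the emission rate at
               planted nucleosomes is multiplied by the depletion factor.
    ``MNase``  phased nucleosomes at every gene (positioning does not
               depend on the variant); fragment lengths spread beyond
               the mono-nucleosome band for downstream length filtering.
    ``PolII``  fragments over active gene bodies, scaled per gene by the
               planted knockdown effect ("DomKD") or the Zld effect at
               Zld-dependent genes ("ZldKD").
    ``input``  uniform coverage, no nucleosome structure.

    Every sample also carries spike-contig fragments at the configured
    spike fraction of its library.
    """
    if assay not in {"H2A.Z", "MNase", "PolII", "input"}:
        raise ValueError(f"unknown assay {assay!r}")
    rng = config.rng(f"chip_{assay}_{condition}")
    frames = []
    for rep in range(1, config.chip_reps + 1):
        n_main = 0
        if assay in ("H2A.Z", "MNase"):
            which = "h2az" if assay == "H2A.Z" else "all"
            depleted = assay == "H2A.Z" and condition == "DomKD"
            rate = config.chip_frags_per_nucleosome * (
                config.depletion_factor if depleted else 1.0
            )
            for chrom, dyad in _nucleosome_positions(truth, which, config):
                n = rng.poisson(rate)
                if n == 0:
                    continue
                dyads = rng.normal(dyad, config.phasing_sd, size=n)
                if assay == "MNase":
                    lengths = rng.integers(*config.mnase_frag_len_range, size=n,
                                           endpoint=True)
                else:
                    lengths = np.full(n, config.nucleosome_frag_len)
                starts = (dyads - lengths / 2.0).astype(int)
                starts, ends = _clip_fragments(starts, lengths, build.lengths[chrom])
                strands = rng.choice(["+", "-"], size=n)
                frames.append(_frame(np.repeat(chrom, n), starts, ends, strands,
                                     assay, condition, rep))
                n_main += n
            if assay == "H2A.Z":
                disp = _dispersed_h2az(rng, build, truth, config, condition, rep)
                n_main += sum(len(f) for f in disp)
                frames += disp
            bg = _uniform_background(rng, build, config.chip_background_per_bp,
                                     config.nucleosome_frag_len, assay, condition, rep)
            n_main += sum(len(f) for f in bg)
            frames += bg
        elif assay == "PolII":
            for r in truth.itertuples():
                if not r.active:
                    continue
                mult = 1.0
                if condition == "ZldKD" and r.zld_dependent:
                    mult = 2.0 ** config.zld_effect_lfc
                elif condition == "DomKD":
                    mult = 2.0 ** r.planted_logFC_kd
                n = rng.poisson(config.polii_frags_per_gene * mult)
                if n == 0:
                    continue
                off = rng.integers(0, max(r.length - config.polii_frag_len, 1), size=n)
                if r.strand == "+":
                    starts = r.tss + off
                else:
                    starts = r.tss - off - (config.polii_frag_len - 1)
                starts, ends = _clip_fragments(starts, config.polii_frag_len,
                                               build.lengths[r.chrom])
                strands = rng.choice(["+", "-"], size=n)
                frames.append(_frame(np.repeat(r.chrom, n), starts, ends, strands,
                                     assay, condition, rep))
                n_main += n
            bg = _uniform_background(rng, build, config.chip_background_per_bp,
                                     config.polii_frag_len, assay, condition, rep)
            n_main += sum(len(f) for f in bg)
            frames += bg
        else:  # input
            bg = _uniform_background(rng, build, config.input_frags_per_bp,
                                     config.nucleosome_frag_len, assay, condition, rep)
            n_main += sum(len(f) for f in bg)
            frames += bg
        frames += _spike_fragments(
            rng, build, config, n_main,
            config.nucleosome_frag_len if assay != "PolII" else config.polii_frag_len,
            assay, condition, rep)
    return FragmentSet(pd.concat(frames, ignore_index=True), build)


def simulate_rnaseq_counts(
    truth: pd.DataFrame,
    config: SimConfig,
    sample_kind: str,
) -> CountMatrix:
    """Negative-binomial RNA counts for unfertilized eggs or embryos.

    Unfertilized samples express maternal genes only; embryo samples
    express active and maternal genes.  Expected counts scale with gene
    length so downstream TPM values behave like real data.
    """
    if sample_kind not in {"unfertilized", "embryo"}:
        raise ValueError(f"unknown sample_kind {sample_kind!r}")
    rng = config.rng(f"rnaseq_{sample_kind}")
    n_reps = (config.rnaseq_unfert_reps if sample_kind == "unfertilized"
              else config.rnaseq_embryo_reps)
    length_kb = truth["length"].to_numpy() / 1_000.0
    if sample_kind == "unfertilized":
        rate = np.where(truth["maternal"], config.rna_maternal_rate,
                        config.rna_background_rate)
    else:
        rate = (config.rna_active_rate * truth["active"].to_numpy()
                + config.rna_maternal_rate * 0.5 * truth["maternal"].to_numpy()
                + config.rna_background_rate)
    mean = rate * length_kb
    disp = config.rna_dispersion
    cols = {}
    for rep in range(1, n_reps + 1):
        p = 1.0 / (1.0 + disp * mean)
        cols[f"{sample_kind}_{rep}"] = rng.negative_binomial(1.0 / disp, p)
    counts = pd.DataFrame(cols, index=truth.index)
    meta = pd.DataFrame(
        {"condition": sample_kind, "replicate": [str(i) for i in range(1, n_reps + 1)]},
        index=list(cols),
    )
    lengths = pd.Series(truth["length"].to_numpy(), index=truth.index, name="length")
    return CountMatrix(counts, meta, lengths)


def planted_boundaries(
    truth: pd.DataFrame, config: SimConfig, build: GenomeBuild
) -> dict[str, list[int]]:
    """Bins of planted TAD boundaries per chromosome (the TSS bins of
    genes flagged ``boundary_near_tss``)."""
    out: dict[str, list[int]] = {}
    for chrom in build.main_chromosomes:
        sel = truth[(truth["chrom"] == chrom) & truth["boundary_near_tss"]]
        out[chrom] = sorted(int(t) // config.hic_bin_size for t in sel["tss"])
    return out


def simulate_contacts(
    truth: pd.DataFrame,
    config: SimConfig,
    build: GenomeBuild,
    condition: str = "Ctrl",
) -> tuple[dict[str, ContactMatrix], dict[str, list[int]]]:
    """Distance-decay contact matrices with planted boundaries.

    Expected counts follow ``scale * d^-decay``; every boundary crossed
    by a bin pair multiplies the expectation by the attenuation factor
    (a boundary "at bin b" separates bins < b from bins >= b).  Counts
    are Poisson sampled and symmetrized.  In the knockdown condition the
    attenuation is weakened (boundaries partially dissolve).
    """
    rng = config.rng(f"hic_{condition}")
    att = config.boundary_attenuation
    if condition != "Ctrl":
        att = att ** config.boundary_weakening_kd
    bounds = planted_boundaries(truth, config, build)
    matrices: dict[str, ContactMatrix] = {}
    for chrom in build.main_chromosomes:
        n = build.lengths[chrom] // config.hic_bin_size
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        expected = config.contact_scale * np.maximum(d, 1) ** (-config.contact_decay)
        cum = np.zeros(n)
        for b in bounds[chrom]:
            cum[b:] += 1
        crossings = np.abs(np.subtract.outer(cum, cum))
        expected = expected * att ** crossings
        upper = rng.poisson(np.triu(expected))
        mat = np.triu(upper) + np.triu(upper, 1).T
        matrices[chrom] = ContactMatrix(chrom, config.hic_bin_size, mat.astype(float))
    return matrices, bounds


def simulate_proteomics(config: SimConfig) -> pd.DataFrame:
    """Two-group log2 LFQ intensity table with MNAR dropout.

    Bait-enriched proteins get the configured fold change; intensities
    are log-normal; values below a global censoring threshold are set
    missing (missing-not-at-random); contaminant / decoy / site-only
    rows are injected and flagged.
    """
    rng = config.rng("proteomics")
    n, reps = config.prot_n, config.prot_reps
    ids = [f"P{i:05d}" for i in range(n)]
    base = rng.normal(config.prot_base_mean, config.prot_base_sd, size=n)
    n_enr = int(round(config.prot_frac_enriched * n))
    enriched = np.zeros(n, dtype=bool)
    enriched[rng.choice(n, size=n_enr, replace=False)] = True

    samples = [f"bait_{i + 1}" for i in range(reps)] + [f"ctrl_{i + 1}" for i in range(reps)]
    groups = ["bait"] * reps + ["control"] * reps
    values = np.empty((n, 2 * reps))
    for j, grp in enumerate(groups):
        mu = base + (config.prot_log2fc if grp == "bait" else 0.0) * enriched
        values[:, j] = rng.normal(mu, config.prot_sd)

    threshold = np.quantile(values, config.prot_censor_quantile)
    values[values < threshold] = np.nan

    table = pd.DataFrame(values, index=ids, columns=samples)
    table["contaminant"] = False
    table["decoy"] = False
    table["site_only"] = False
    table["planted_enriched"] = enriched

    def _junk(prefix, flag, count):
        junk = pd.DataFrame(
            rng.normal(config.prot_base_mean, config.prot_base_sd, size=(count, 2 * reps)),
            index=[f"{prefix}{i:03d}" for i in range(count)], columns=samples,
        )
        junk["contaminant"] = flag == "contaminant"
        junk["decoy"] = flag == "decoy"
        junk["site_only"] = flag == "site_only"
        junk["planted_enriched"] = False
        return junk

    table = pd.concat([
        table,
        _junk("CON_", "contaminant", config.prot_n_contaminants),
        _junk("REV_", "decoy", config.prot_n_decoys),
        _junk("SITE_", "site_only", config.prot_n_site_only),
    ])
    table.attrs["groups"] = dict(zip(samples, groups))
    return table


def write_truth(path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t")


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
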