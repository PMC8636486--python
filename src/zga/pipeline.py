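"""End-to-end orchestration: simulate (or load) -> promoter activity ->
Zld dependence -> H2A.Z classes -> differential by class -> insulation by
class -> report.

Stages communicate only through the declared data containers / file
formats, so each one can be re-run in isolation.  Every threshold sits
in :class:`Thresholds` (the ``paper_defaults`` config section) and can
be overridden from YAML.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields, replace

import numpy as np
import pandas as pd

from . import activity, differential, expression, insulation, nucleosome
from .genome import transcripts_frame
from .synthetic import SimConfig, simulate_chip, simulate_contacts, simulate_groseq, \
    simulate_rnaseq_counts, simulate_truth_genome

log = logging.getLogger(__name__)

CLASS_LABELS = ("zld_dep", "h2az_pos", "h2az_neg_minus1", "h2az_neg_none")


@dataclass(frozen=True)
class Thresholds:
    """Every rule threshold of the classification pipeline in one place."""

    peak_q_max: float = 0.05
    peak_extsize: int = 100
    activity_max_dist: int = 150          # nt, summit to TSS
    promoter_window: int = 150            # nt, unique-promoter clustering
    blacklist_merge_dist: int = 1_000
    blacklist_span_min: int = 12_000
    flank_r1_max: int = 350               # nt, single-replicate dyad rule
    flank_r2_max: int = 600               # nt, both-replicate dyad rule
    flank_r2_diff: int = 80               # nt, max center difference
    mnase_len_lo: int = 130
    mnase_len_hi: int = 200
    tpm_threshold: float = 5.0
    tpm_min_reps: int = 3
    zld_lfc_max: float = -1.0
    zld_fdr_max: float = 0.01
    diff_min_mean: float = 10.0
    transcript_min_span: int = 125
    transcript_min_sum: int = 10
    relacs_flank: int = 400               # promoter window +/- nt
    bin_size: int = 500
    bin_min_mean: float = 25.0
    hic_min_depth: int = 20_000
    hic_max_depth: int = 100_000
    hic_step: int = 2_000
    boundary_delta: float = 0.01
    ipms_width: float = 0.5
    ipms_downshift: float = 1.8
    ipms_padj_max: float = 0.05
    ipms_fc_min: float = 1.5


def _config_hash(sim: SimConfig, thr: Thresholds) -> str:
    payload = json.dumps({"sim": asdict(sim), "thresholds": asdict(thr)},
                         sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> tuple[SimConfig, Thresholds]:
    """Build SimConfig + Thresholds from a YAML file with ``simulate:``
    and ``paper_defaults:`` sections (missing keys fall back to defaults)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim_kw = raw.get("simulate", {}) or {}
    thr_kw = raw.get("paper_defaults", {}) or {}
    valid_sim = {f.name for f in fields(SimConfig)}
    valid_thr = {f.name for f in fields(Thresholds)}
    bad = (set(sim_kw) - valid_sim) | (set(thr_kw) - valid_thr)
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    sim = SimConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                       for k, v in sim_kw.items()})
    return sim, Thresholds(**thr_kw)


def run_pipeline(
    sim: SimConfig,
    thresholds: Thresholds | None = None,
    with_hic: bool = True,
    with_relacs: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Run the full synthetic analysis and classify every promoter.

    Returns the per-promoter classification table (with rule provenance)
    and a machine-readable run summary.  ``with_hic`` / ``with_relacs``
    switch off the heavier quantitative stages when only the promoter
    classification is needed.
    """
    thr = thresholds or Thresholds()
    t0 = time.time()

    def stamp(stage: str) -> None:
        log.info("stage %-22s %6.1f s", stage, time.time() - t0)

    build, transcripts, truth = simulate_truth_genome(sim)
    tdf = transcripts_frame(transcripts)
    stamp("simulate_truth")

    # --- promoter activity from nascent transcription (pooled Ctrl reps)
    gro_ctrl = simulate_groseq(truth, sim, build, "Ctrl")
    cov = activity.strand_coverage(gro_ctrl, extsize=thr.peak_extsize)
    peaks = activity.call_peaks(cov, q_max=thr.peak_q_max, extsize=thr.peak_extsize)
    promoters = activity.select_unique_promoters(tdf, window=thr.promoter_window)
    act = activity.assign_activity(promoters, peaks, max_dist=thr.activity_max_dist)
    stamp("activity")

    # --- Zld dependence from differential Pol II occupancy (Ctrl vs ZldKD)
    pol_ctrl = simulate_chip(truth, sim, build, "PolII", "Ctrl")
    pol_zld = simulate_chip(truth, sim, build, "PolII", "ZldKD")
    pol = pol_ctrl.concat([pol_ctrl, pol_zld])
    pol_cm, _pol_fpkm = differential.transcript_counts_fpkm(
        pol, tdf, min_span=thr.transcript_min_span, min_sum=thr.transcript_min_sum)
    lib = pol_cm.counts.sum(axis=0).astype(float)
    pol_sf = lib / np.exp(np.log(lib).mean())
    pol_diff = differential.nb_differential(
        pol_cm, pol_sf, condition_ref="Ctrl", min_mean=thr.diff_min_mean)
    zld_transcripts = differential.call_zld_dependent(
        pol_diff, lfc_max=thr.zld_lfc_max, fdr_max=thr.zld_fdr_max)
    zld_genes = set(tdf.loc[[t for t in zld_transcripts if t in tdf.index], "gene_id"])
    stamp("zld_dependence")

    # --- H2A.Z classes from replicate dyad calls
    h2az_ctrl = simulate_chip(truth, sim, build, "H2A.Z", "Ctrl")
    dyads = {
        rep: nucleosome.call_dyads(h2az_ctrl.subset(replicate=str(rep)))
        for rep in (1, 2)
    }
    flanks = nucleosome.assign_all_flanks(
        promoters, dyads[1], dyads[2],
        r1_max=thr.flank_r1_max, r2_max=thr.flank_r2_max, r2_diff=thr.flank_r2_diff)
    stamp("h2az_dyads")

    # --- maternal / zygotic origin
    unfert = simulate_rnaseq_counts(truth, sim, "unfertilized")
    embryo = simulate_rnaseq_counts(truth, sim, "embryo")
    tpm_unfert = expression.compute_tpm(unfert)
    tpm_embryo = expression.compute_tpm(embryo)
    maternal = expression.maternal_set(
        tpm_unfert, threshold=thr.tpm_threshold, min_reps=thr.tpm_min_reps)
    active_genes = set(promoters.loc[act["active"], "gene_id"])
    origin = expression.origin_classify(maternal, active_genes, truth.index)
    zelda_targets = expression.zelda_zygotic_targets(
        tpm_embryo, zld_genes, origin, active_genes, threshold=thr.tpm_threshold)
    stamp("origin")

    # --- classification table
    table = promoters.copy()
    table["active"] = act["active"]
    table["activity_peak"] = act["supporting_peak"]
    table["blacklisted"] = act["blacklisted"]
    table["zld_dependent"] = table["gene_id"].isin(zld_genes) & table["active"]
    table = table.join(
        nucleosome.classify_h2az(promoters, flanks, zld_dependent=table["zld_dependent"])
    )
    table["origin"] = origin.reindex(table["gene_id"]).to_numpy()
    table["zelda_zygotic_target"] = table["gene_id"].isin(zelda_targets)

    def final_class(row):
        if not row["active"]:
            return "inactive"
        if row["zld_dependent"]:
            return "zld_dep"
        return row["h2az_class"]

    table["class"] = table.apply(final_class, axis=1)

    # --- differential nascent transcription by class (Ctrl vs DomKD),
    #     normalized on the Zelda-zygotic-target reference set
    gro_kd = simulate_groseq(truth, sim, build, "DomKD")
    gro = gro_ctrl.concat([gro_ctrl, gro_kd])
    gro_cm, _ = differential.transcript_counts_fpkm(
        gro, tdf, min_span=thr.transcript_min_span, min_sum=thr.transcript_min_sum,
        stranded=True)
    ref_transcripts = [t for t in gro_cm.counts.index
                       if tdf.loc[t, "gene_id"] in zelda_targets]
    if len(ref_transcripts) >= 5:
        sf = differential.reference_size_factors(gro_cm, ref_transcripts)
    else:  # degenerate reference: fall back to library-size factors
        lib = gro_cm.counts.sum(axis=0).astype(float)
        sf = lib / np.exp(np.log(lib).mean())
        log.warning("Zelda-zygotic reference too small (%d); library-size factors used",
                    len(ref_transcripts))
    gro_diff = differential.nb_differential(
        gro_cm, sf, condition_ref="Ctrl", min_mean=thr.diff_min_mean)
    table["groseq_logFC_kd"] = gro_diff["logFC"].reindex(table.index).to_numpy()
    stamp("differential_kd")

    summary: dict = {
        "config": {"sim": asdict(sim), "thresholds": asdict(thr)},
        "config_hash": _config_hash(sim, thr),
        "seed": sim.seed,
    }

    # --- quantitative H2A.Z scaling (double ratio over active promoters)
    if with_relacs:
        h2az_kd = simulate_chip(truth, sim, build, "H2A.Z", "DomKD")
        ip = h2az_ctrl.concat([h2az_ctrl, h2az_kd])
        inp_ctrl = simulate_chip(truth, sim, build, "input", "Ctrl")
        inp_kd = simulate_chip(truth, sim, build, "input", "DomKD")
        inp = inp_ctrl.concat([inp_ctrl, inp_kd])
        regions = pd.DataFrame(
            {
                "chrom": table.loc[table["active"], "chrom"],
                "start": np.maximum(table.loc[table["active"], "tss"] - thr.relacs_flank, 0),
                "end": table.loc[table["active"], "tss"] + thr.relacs_flank,
            }
        )
        summary["relacs_double_ratio"] = differential.relacs_from_fragments(
            ip, inp, regions)
        stamp("relacs")

    # --- TAD insulation by class
    if with_hic:
        mats_ctrl, bounds = simulate_contacts(truth, sim, build, "Ctrl")
        mats_kd, _ = simulate_contacts(truth, sim, build, "DomKD")
        tracks = {}
        for name, mats in (("Ctrl", mats_ctrl), ("DomKD", mats_kd)):
            per_chrom = []
            for chrom, m in mats.items():
                insulation.balance(m)
                per_chrom.append(insulation.insulation_score(
                    m, min_depth=thr.hic_min_depth, max_depth=thr.hic_max_depth,
                    step=thr.hic_step))
            tracks[name] = pd.concat(per_chrom, ignore_index=True)
        diff_track = insulation.insulation_difference(tracks["DomKD"], tracks["Ctrl"])
        bounds_called = insulation.call_boundaries(tracks["Ctrl"], delta=thr.boundary_delta)

        def tss_score(track):
            by_chrom = {c: s.reset_index(drop=True) for c, s in track.groupby("chrom")}
            vals = []
            for _, row in table.iterrows():
                sub = by_chrom.get(row["chrom"])
                b = int(row["tss"]) // sim.hic_bin_size
                vals.append(sub["score"].iloc[b] if sub is not None and b < len(sub)
                            else np.nan)
            return pd.Series(vals, index=table.index)

        table["insulation_ctrl"] = tss_score(tracks["Ctrl"])
        table["insulation_change_kd"] = tss_score(diff_track)
        table["boundary_distance"] = insulation.boundary_distance(
            table, bounds_called, sim.hic_bin_size).to_numpy()
        stamp("insulation")

    # --- summary
    active_tab = table[table["active"]]
    n_active = int(len(active_tab))
    classes = {}
    for label in CLASS_LABELS:
        sub = active_tab[active_tab["class"] == label]
        entry = {
            "promoters": int(len(sub)),
            "genes": int(sub["gene_id"].nunique()),
            "fraction_of_active": (len(sub) / n_active) if n_active else 0.0,
            "median_logFC_kd": float(np.nanmedian(sub["groseq_logFC_kd"]))
            if sub["groseq_logFC_kd"].notna().any() else None,
        }
        if with_hic:
            entry["median_tss_insulation"] = (
                float(np.nanmedian(sub["insulation_ctrl"]))
                if sub["insulation_ctrl"].notna().any() else None)
            entry["median_insulation_change_kd"] = (
                float(np.nanmedian(sub["insulation_change_kd"]))
                if sub["insulation_change_kd"].notna().any() else None)
            entry["median_boundary_distance"] = (
                float(np.nanmedian(sub["boundary_distance"]))
                if sub["boundary_distance"].notna().any() else None)
        classes[label] = entry
    summary.update(
        {
            "n_promoters": int(len(table)),
            "n_active_promoters": n_active,
            "n_active_genes": int(active_tab["gene_id"].nunique()),
            "n_zelda_zygotic_targets": int(len(zelda_targets)),
            "classes": classes,
            "h2az_pos_fraction_of_active_genes": (
                classes["h2az_pos"]["genes"] / int(active_tab["gene_id"].nunique())
                if n_active else 0.0),
            "partition_ok": n_active == sum(
                classes[label]["promoters"] for label in CLASS_LABELS),
        }
    )
    stamp("done")
    return table, summary


def write_report(summary: dict, json_path, text_path=None) -> None:
    """Write the run summary as JSON (stable keys) and a short text digest."""
    with open(json_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    if text_path is not None:
        lines = [
            f"promoters          {summary['n_promoters']}",
            f"active promoters   {summary['n_active_promoters']} "
            f"({summary['n_active_genes']} genes)",
        ]
        for label in CLASS_LABELS:
            c = summary["classes"][label]
            lines.append(
                f"  {label:<16} {c['promoters']:>5} promoters  "
                f"{100 * c['fraction_of_active']:5.1f}% of active"
            )
        if "relacs_double_ratio" in summary:
            lines.append(f"RELACS double ratio {summary['relacs_double_ratio']:.3f}")
        with open(text_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def partition_counts(n_zld: int, n_independent: int) -> int:
    """Total active promoters as the sum of the Zld-dependent and
    Zld-independent partitions."""
    if n_zld < 0 or n_independent < 0:
        raise ValueError("counts must be non-negative")
    return n_zld + n_independent


def fraction_percent(part: int, whole: int) -> float:
    """100 * part / whole, the headline 'share of active genes' arithmetic."""
    if whole <= 0:
        raise ValueError("whole must be positive")
    if part < 0 or part > whole:
        raise ValueError("part outside [0, whole]")
    return 100.0 * part / whole
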