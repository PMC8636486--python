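"""Nucleosome dyad calling and +1/-1 H2A.Z promoter classification.

Dyads are local maxima of a Gaussian-smoothed fragment-midpoint density.
Flanking (+1 downstream / -1 upstream) nucleosomes are assigned per
promoter with two replicate-consistency rules:

rule 1  a dyad within 350 nt of the TSS in at least one replicate;
rule 2  dyads within 600 nt in *both* replicates whose centers differ by
        less than 80 nt (the assigned position is their midpoint).

Rule 1 is evaluated first; the rules combine by OR.  A promoter is
H2A.Z-positive iff it has a +1 assignment; otherwise it is
H2A.Z-negative with or without a -1 nucleosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .genome import FragmentSet, signed_offset

H2AZ_POS = "h2az_pos"
H2AZ_NEG_MINUS1 = "h2az_neg_minus1"
H2AZ_NEG_NONE = "h2az_neg_none"


def filter_fragment_length(fragments: FragmentSet, lo: int = 130, hi: int = 200) -> FragmentSet:
    """Keep fragments with lo <= length <= hi (both inclusive)."""
    lengths = fragments.lengths
    keep = (lengths >= lo) & (lengths <= hi)
    return FragmentSet(fragments.frame[keep], fragments.build)


def call_dyads(
    fragments: FragmentSet,
    bandwidth: float = 30.0,
    min_separation: int = 120,
    min_rel_occupancy: float = 2.0,
    min_fragments: float = 5.0,
) -> pd.DataFrame:
    """Call nucleosome dyads from fragment midpoints.

    Midpoints are histogrammed per chromosome and smoothed with a
    Gaussian kernel (sd = ``bandwidth`` bp); dyads are local maxima of
    the density that exceed ``min_rel_occupancy`` times the chromosome
    median density *and* an absolute support floor of ``min_fragments``
    effective fragments (peak height x bandwidth x sqrt(2 pi)); maxima
    are kept greedily in decreasing occupancy subject to
    ``min_separation``.  Occupancy is reported in effective-fragment
    units.  Spike contigs are ignored.
    """
    rows = []
    build = fragments.build
    kernel_mass = bandwidth * np.sqrt(2.0 * np.pi)
    frame = fragments.frame
    mids_all = fragments.midpoints
    for chrom in build.main_chromosomes:
        L = build.lengths[chrom]
        mids = mids_all[(frame["chrom"] == chrom).to_numpy()]
        if len(mids) == 0:
            continue
        hist = np.bincount(mids, minlength=L).astype(float)
        density = gaussian_filter1d(hist, sigma=bandwidth)
        med = np.median(density)
        floor = med if med > 0 else density.mean()
        threshold = max(min_rel_occupancy * floor, min_fragments / kernel_mass)
        peaks, props = find_peaks(density, height=threshold, distance=min_separation)
        for pos, h in zip(peaks, props["peak_heights"]):
            rows.append((chrom, int(pos), float(h * kernel_mass)))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "occupancy"])
    return df.sort_values(["chrom", "pos"]).reset_index(drop=True)


@dataclass(frozen=True)
class FlankCall:
    position: int
    rule: str            # "r1_single" or "r2_both"
    offset: int          # signed, strand-aware


def _directional(dyads: pd.DataFrame, chrom: str, tss: int, strand: str, direction: str):
    sub = dyads[dyads["chrom"] == chrom]
    off = signed_offset(sub["pos"].to_numpy(), tss, strand)
    if direction == "downstream":
        keep = off >= 0
    elif direction == "upstream":
        keep = off < 0
    else:
        raise ValueError(f"bad direction {direction!r}")
    return sub["pos"].to_numpy()[keep], off[keep]


def assign_flanking(
    tss: int,
    strand: str,
    chrom: str,
    calls_rep1: pd.DataFrame,
    calls_rep2: pd.DataFrame,
    direction: str,
    r1_max: int = 350,
    r2_max: int = 600,
    r2_diff: int = 80,
) -> FlankCall | None:
    """Assign a +1 (downstream) or -1 (upstream) nucleosome to one promoter.

    Rule 1: nearest qualifying dyad with |offset| <= ``r1_max`` in either
    replicate.  Rule 2: nearest dyads with |offset| <= ``r2_max`` in both
    replicates whose centers differ by < ``r2_diff``; the assigned
    position is their midpoint.  Rule 1 wins when it fires; ties on
    |offset| break to the leftmost genomic position.
    """
    pos1, off1 = _directional(calls_rep1, chrom, tss, strand, direction)
    pos2, off2 = _directional(calls_rep2, chrom, tss, strand, direction)

    pool_pos = np.concatenate([pos1, pos2])
    pool_off = np.concatenate([off1, off2])
    near = np.abs(pool_off) <= r1_max
    if near.any():
        cand_pos, cand_off = pool_pos[near], pool_off[near]
        order = np.lexsort((cand_pos, np.abs(cand_off)))
        k = order[0]
        return FlankCall(int(cand_pos[k]), "r1_single", int(cand_off[k]))

    in1 = np.abs(off1) <= r2_max
    in2 = np.abs(off2) <= r2_max
    if in1.any() and in2.any():
        k1 = np.lexsort((pos1[in1], np.abs(off1[in1])))[0]
        k2 = np.lexsort((pos2[in2], np.abs(off2[in2])))[0]
        p1, p2 = int(pos1[in1][k1]), int(pos2[in2][k2])
        if abs(p1 - p2) < r2_diff:
            mid = (p1 + p2) // 2
            return FlankCall(mid, "r2_both", int(signed_offset(mid, tss, strand)))
    return None


def assign_all_flanks(
    promoters: pd.DataFrame,
    calls_rep1: pd.DataFrame,
    calls_rep2: pd.DataFrame,
    **rule_kw,
) -> pd.DataFrame:
    """Vector version of :func:`assign_flanking` over a promoter table.

    ``promoters`` needs columns chrom, strand, tss.  Returns per-promoter
    plus1/minus1 positions, rules and signed offsets (NaN where absent).
    """
    out = {}
    for direction, prefix in (("downstream", "plus1"), ("upstream", "minus1")):
        pos, rule, off = [], [], []
        for _, row in promoters.iterrows():
            call = assign_flanking(
                int(row["tss"]), row["strand"], row["chrom"],
                calls_rep1, calls_rep2, direction, **rule_kw,
            )
            pos.append(call.position if call else np.nan)
            rule.append(call.rule if call else pd.NA)
            off.append(call.offset if call else np.nan)
        out[f"{prefix}_pos"] = pos
        out[f"{prefix}_rule"] = rule
        out[f"{prefix}_offset"] = off
    return pd.DataFrame(out, index=promoters.index)


def classify_h2az(
    promoters: pd.DataFrame,
    flanks: pd.DataFrame,
    zld_dependent: pd.Series | None = None,
) -> pd.DataFrame:
    """Partition promoters into H2A.Z-positive / -negative classes.

    H2A.Z-positive iff a +1 assignment exists; else negative with a -1
    nucleosome; else negative without.  Zld-dependent promoters are
    excluded from the partition (label NA) but keep their flank calls.
    """
    label = pd.Series(H2AZ_NEG_NONE, index=promoters.index, dtype="object")
    label[flanks["minus1_pos"].notna()] = H2AZ_NEG_MINUS1
    label[flanks["plus1_pos"].notna()] = H2AZ_POS
    if zld_dependent is not None:
        label[zld_dependent.reindex(promoters.index).fillna(False).astype(bool)] = pd.NA
    out = flanks.copy()
    out["h2az_class"] = label
    return out
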