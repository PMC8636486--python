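"""Promoter activity from strand-specific nascent transcription.

A promoter is called active when a strand-matched enriched region
(peak) of pooled nascent-transcription coverage has its summit within a
fixed distance of the TSS.  Peak calling is a self-contained Poisson
scan: per-base coverage of 5'-extended fragments is screened against a
genome-wide background rate, candidate regions are scored at their
summit against a local background, and Benjamini-Hochberg q-values are
computed with the track length (in extension-size units) as the number
of tests, so that flat background yields no peaks.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genome import FragmentSet, GenomeBuild, Interval

log = logging.getLogger(__name__)

PEAK_COLUMNS = ["chrom", "start", "end", "strand", "summit", "height", "pvalue", "qvalue"]


def strand_coverage(
    fragments: FragmentSet, extsize: int = 100
) -> dict[tuple[str, str], np.ndarray]:
    """Per-base coverage of 5' ends extended ``extsize`` bp in strand direction.

    Replicates present in the fragment set are pooled.  Returns a dense
    int array per (chromosome, strand); spike contigs are skipped.
    """
    if extsize <= 0:
        raise ValueError("extsize must be positive")
    build = fragments.build
    out: dict[tuple[str, str], np.ndarray] = {}
    frame = fragments.frame
    for chrom in build.main_chromosomes:
        L = build.lengths[chrom]
        sub = frame[frame["chrom"] == chrom]
        for strand in ("+", "-"):
            diff = np.zeros(L + 1, dtype=np.int64)
            rows = sub[sub["strand"] == strand]
            if len(rows):
                if strand == "+":
                    p5 = rows["start"].to_numpy()
                    lo = np.clip(p5, 0, L)
                    hi = np.clip(p5 + extsize, 0, L)
                else:
                    p5 = rows["end"].to_numpy() - 1
                    lo = np.clip(p5 - extsize + 1, 0, L)
                    hi = np.clip(p5 + 1, 0, L)
                np.add.at(diff, lo, 1)
                np.add.at(diff, hi, -1)
            out[(chrom, strand)] = np.cumsum(diff[:-1])
    return out


def _candidate_regions(cov: np.ndarray, threshold: float, merge_gap: int):
    """Maximal runs of coverage >= threshold, merged across small gaps."""
    above = cov >= threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        ends = ends + [len(cov)]
    merged = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return merged


def call_peaks(
    coverage: dict[tuple[str, str], np.ndarray],
    q_max: float = 0.05,
    extsize: int = 100,
    prefilter_p: float = 1e-3,
    local_windows: tuple[int, int] = (1_000, 10_000),
) -> pd.DataFrame:
    """Poisson-background peak calling on per-strand coverage tracks.

    Candidate regions are bases whose coverage is implausible under the
    genome-wide Poisson rate (at ``prefilter_p``), merged across gaps of
    ``extsize``.  Each region is scored by the Poisson tail of its summit
    height against lambda_local = max(lambda_genome, lambda_1kb,
    lambda_10kb), the local rates computed with the region itself
    excluded.  BH correction uses total track length / extsize as the
    test count; regions with q <= q_max are kept.  Summit ties break
    leftmost.
    """
    records = []
    m_tests = 0
    for (chrom, strand), cov in coverage.items():
        L = len(cov)
        m_tests += max(L // extsize, 1)
        lam_genome = cov.mean()
        if lam_genome == 0:
            continue
        threshold = stats.poisson.ppf(1.0 - prefilter_p, lam_genome) + 1
        csum = np.concatenate([[0], np.cumsum(cov, dtype=np.float64)])
        for s, e in _candidate_regions(cov, threshold, extsize):
            summit = s + int(np.argmax(cov[s:e]))
            height = int(cov[summit])
            region_sum = csum[e] - csum[s]
            lams = [lam_genome]
            for w in local_windows:
                lo = max(summit - w // 2, 0)
                hi = min(summit + w // 2, L)
                window_sum = csum[hi] - csum[lo]
                outside = (hi - lo) - (min(e, hi) - max(s, lo))
                if outside > 0:
                    inside = csum[min(e, hi)] - csum[max(s, lo)]
                    lams.append((window_sum - inside) / outside)
            lam_local = max(lams)
            p = stats.poisson.sf(height - 1, lam_local)
            records.append((chrom, s, e, strand, summit, height, p))
    if not records:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    df = pd.DataFrame(records, columns=PEAK_COLUMNS[:-1])
    m = max(m_tests, len(df))
    order = np.argsort(df["pvalue"].to_numpy(), kind="stable")
    q = df["pvalue"].to_numpy()[order] * m / np.arange(1, len(df) + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    qvals = np.empty(len(df))
    qvals[order] = np.minimum(q, 1.0)
    df["qvalue"] = qvals
    df = df[df["qvalue"] <= q_max].reset_index(drop=True)
    return df


def blacklist_hyperaccessible(
    atac_peaks: pd.DataFrame | list[Interval],
    merge_dist: int = 1_000,
    span_min: int = 12_000,
) -> list[Interval]:
    """Merge accessibility peaks within ``merge_dist`` and emit merged
    regions spanning strictly more than ``span_min`` bp as a blacklist."""
    if isinstance(atac_peaks, pd.DataFrame):
        peaks = [Interval(r.chrom, int(r.start), int(r.end))
                 for r in atac_peaks.itertuples()]
    else:
        peaks = list(atac_peaks)
    out: list[Interval] = []
    by_chrom: dict[str, list[Interval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom, ps in by_chrom.items():
        ps.sort(key=lambda p: p.start)
        cur_s, cur_e = ps[0].start, ps[0].end
        merged = []
        for p in ps[1:]:
            if p.start - cur_e <= merge_dist:
                cur_e = max(cur_e, p.end)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = p.start, p.end
        merged.append((cur_s, cur_e))
        for s, e in merged:
            if e - s > span_min:
                out.append(Interval(chrom, s, e))
    return out


def assign_activity(
    promoters: pd.DataFrame,
    peaks: pd.DataFrame,
    max_dist: int = 150,
    blacklist: list[Interval] | None = None,
) -> pd.DataFrame:
    """Call each promoter active iff a same-strand peak summit lies within
    ``max_dist`` bp (inclusive) of its TSS.

    ``promoters`` needs columns chrom, strand, tss (index = promoter id).
    Promoters inside a blacklist interval are flagged and never active.
    Returns active / supporting_peak / distance_to_summit / blacklisted.
    """
    result = pd.DataFrame(
        {
            "active": False,
            "supporting_peak": pd.Series(pd.NA, index=promoters.index, dtype="object"),
            "distance_to_summit": np.nan,
            "blacklisted": False,
        },
        index=promoters.index,
    )
    black_by_chrom: dict[str, list[Interval]] = {}
    for iv in blacklist or []:
        black_by_chrom.setdefault(iv.chrom, []).append(iv)

    grouped: dict[tuple[str, str], pd.DataFrame] = {
        key: grp.reset_index() for key, grp in peaks.groupby(["chrom", "strand"])
    } if len(peaks) else {}

    for pid, row in promoters.iterrows():
        tss = int(row["tss"])
        for iv in black_by_chrom.get(row["chrom"], []):
            if iv.start <= tss < iv.end:
                result.loc[pid, "blacklisted"] = True
                break
        if result.loc[pid, "blacklisted"]:
            continue
        grp = grouped.get((row["chrom"], row["strand"]))
        if grp is None or not len(grp):
            continue
        dist = np.abs(grp["summit"].to_numpy() - tss)
        k = int(np.argmin(dist))
        if dist[k] <= max_dist:
            result.loc[pid, "active"] = True
            result.loc[pid, "supporting_peak"] = f"{row['chrom']}:{int(grp.loc[k, 'summit'])}:{row['strand']}"
            result.loc[pid, "distance_to_summit"] = float(dist[k])
    return result


def select_unique_promoters(
    transcripts_df: pd.DataFrame,
    diff_results: pd.DataFrame | None = None,
    window: int = 150,
) -> pd.DataFrame:
    """Collapse transcripts to unique promoters.

    Transcripts of the same gene whose promoter windows (TSS +/- window)
    overlap on the same strand form one promoter cluster; the
    representative is the transcript with the smallest FDR in
    ``diff_results`` (column "fdr") when given, else the most upstream
    TSS.  Clusters whose merged window overlaps a cluster of a
    *different* gene on the same strand are discarded as non-unique.

    ``transcripts_df`` is the frame from :func:`zga.genome.transcripts_frame`.
    Returns one row per retained promoter, indexed by representative
    transcript id.
    """
    clusters = []  # (chrom, strand, win_lo, win_hi, gene_id, members)
    for (gene, chrom, strand), grp in transcripts_df.groupby(
        ["gene_id", "chrom", "strand"]
    ):
        grp = grp.sort_values("tss")
        cur: list[str] = []
        lo = hi = None
        for tid, row in grp.iterrows():
            w_lo, w_hi = row["tss"] - window, row["tss"] + window + 1
            if cur and w_lo <= hi:
                hi = max(hi, w_hi)
                cur.append(tid)
            else:
                if cur:
                    clusters.append((chrom, strand, lo, hi, gene, cur))
                cur, lo, hi = [tid], w_lo, w_hi
        if cur:
            clusters.append((chrom, strand, lo, hi, gene, cur))

    # cross-gene uniqueness: discard clusters overlapping another gene's cluster
    keep = [True] * len(clusters)
    by_key: dict[tuple[str, str], list[int]] = {}
    for i, c in enumerate(clusters):
        by_key.setdefault((c[0], c[1]), []).append(i)
    for idxs in by_key.values():
        idxs.sort(key=lambda i: clusters[i][2])
        for pos, a in enumerate(idxs):
            for b in idxs[pos + 1:]:
                if clusters[b][2] >= clusters[a][3]:
                    break
                if clusters[a][4] != clusters[b][4]:
                    keep[a] = keep[b] = False

    rows = []
    for ok, (chrom, strand, lo, hi, gene, members) in zip(keep, clusters):
        if not ok:
            continue
        if diff_results is not None and "fdr" in diff_results.columns:
            fdrs = diff_results["fdr"].reindex(members)
            rep = fdrs.idxmin() if fdrs.notna().any() else members[0]
        else:
            sub = transcripts_df.loc[members]
            rep = (sub["tss"].idxmin() if strand == "+" else sub["tss"].idxmax())
        rows.append((rep, gene, chrom, strand, int(transcripts_df.loc[rep, "tss"]),
                     len(members)))
    out = pd.DataFrame(
        rows, columns=["promoter_id", "gene_id", "chrom", "strand", "tss", "n_transcripts"]
    ).set_index("promoter_id")
    return out
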