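"""Differential occupancy/expression statistics and quantitative scaling.

One negative-binomial engine serves every count-based comparison in the
pipeline: per-feature dispersion by method of moments, an NB generalized
linear model fitted by iteratively reweighted least squares, and a Wald
test on the condition coefficient with a small-sample t reference.
Normalization comes from reference-set median-of-ratios size factors,
input-only factors, or spike-in factors depending on the assay.  The
quantitative-ChIP double ratio compares IP/input rates across
conditions over a fixed region set and is invariant to sequencing
depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import CountMatrix, FragmentSet, GenomeBuild


# ---------------------------------------------------------------------------
# size factors

def reference_size_factors(cm: CountMatrix, reference: set[str] | list[str]) -> pd.Series:
    """Median-of-ratios size factors computed on a reference feature set.

    Reference features with a zero count in any sample are excluded from
    the geometric mean.  Factors are not rescaled, so identical samples
    get factors of exactly 1 and scaling one sample's counts by c scales
    its factor by c.
    """
    ref = [f for f in reference if f in cm.counts.index]
    sub = cm.counts.loc[ref].to_numpy(dtype=float)
    usable = (sub > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no reference feature has nonzero counts in every sample")
    sub = sub[usable]
    log_geo = np.log(sub).mean(axis=1)
    ratios = np.log(sub) - log_geo[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def spikein_size_factors(spike_counts: pd.Series) -> pd.Series:
    """Per-sample factors proportional to 1 / spike-in count, normalized
    to geometric mean 1.  A sample without spike-in reads is an error."""
    c = spike_counts.astype(float)
    if (c <= 0).any():
        bad = list(spike_counts.index[c <= 0])
        raise ValueError(f"zero spike-in counts in samples {bad}")
    f = 1.0 / c
    f /= np.exp(np.log(f).mean())
    return pd.Series(f, index=spike_counts.index, name="size_factor")


# ---------------------------------------------------------------------------
# negative-binomial differential testing

def _moments_dispersion(counts: np.ndarray, sf: np.ndarray, groups: np.ndarray,
                        floor: float = 1e-8) -> np.ndarray:
    """Per-feature NB dispersion from normalized within-group moments."""
    q = counts / sf  # features x samples
    num = np.zeros(counts.shape[0])
    den = np.zeros(counts.shape[0])
    for g in np.unique(groups):
        cols = groups == g
        if cols.sum() < 2:
            continue
        m = q[:, cols].mean(axis=1)
        v = q[:, cols].var(axis=1, ddof=1)
        # subtract the Poisson part (scaled by mean inverse size factor)
        shot = m * np.mean(1.0 / sf[cols])
        num += np.maximum(v - shot, 0.0) * (cols.sum() - 1)
        den += m ** 2 * (cols.sum() - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(den > 0, num / den, 0.0)
    return np.maximum(alpha, floor)


def nb_differential(
    cm: CountMatrix,
    size_factors: pd.Series,
    condition_ref: str | None = None,
    min_mean: float = 10.0,
    include_replicate: bool = False,
) -> pd.DataFrame:
    """Negative-binomial Wald test of condition on every feature.

    Features whose mean count across all samples is below ``min_mean``
    are removed.  Dispersion is per-feature method of moments (floor
    1e-8); the NB GLM (log link, log size factors as offset) is fitted
    by IRLS; the Wald statistic on the condition coefficient is referred
    to a t distribution with residual degrees of freedom; BH correction.
    logFC is log2 of the non-reference condition over the reference.
    """
    conditions = cm.meta["condition"]
    levels = list(pd.unique(conditions))
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 conditions, got {levels}")
    if condition_ref is None:
        condition_ref = levels[0]
    other = [l for l in levels if l != condition_ref][0]
    for lv in levels:
        if (conditions == lv).sum() < 2:
            raise ValueError(f"condition {lv!r} has fewer than 2 samples")

    counts = cm.counts.to_numpy(dtype=float)
    keep = counts.mean(axis=1) >= min_mean
    counts = counts[keep]
    features = cm.counts.index[keep]
    sf = size_factors.reindex(cm.counts.columns).to_numpy(dtype=float)
    cond = (conditions == other).astype(float).to_numpy()

    X = [np.ones_like(cond), cond]
    names = ["intercept", "condition"]
    if include_replicate:
        reps = pd.get_dummies(cm.meta["replicate"], drop_first=True)
        for col in reps.columns:
            X.append(reps[col].to_numpy(dtype=float))
            names.append(f"rep_{col}")
    X = np.column_stack(X)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    df_resid = X.shape[0] - X.shape[1]
    offset = np.log(sf)
    alphas = _moments_dispersion(counts, sf, conditions.to_numpy())

    coefs = np.empty(len(features))
    ses = np.empty(len(features))
    means = counts.mean(axis=1)
    for i in range(len(features)):
        fam = sm.families.NegativeBinomial(alpha=float(alphas[i]))
        try:
            res = sm.GLM(counts[i], X, family=fam, offset=offset).fit()
            coefs[i], ses[i] = res.params[1], res.bse[1]
        except Exception:
            coefs[i], ses[i] = np.nan, np.nan
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = coefs / ses
    p = 2.0 * stats.t.sf(np.abs(tstat), df=df_resid)
    p = np.where(np.isfinite(p), p, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "logFC": coefs / np.log(2.0),
            "p": p,
            "fdr": fdr,
            "mean": means,
        },
        index=features,
    )


def call_zld_dependent(
    diff: pd.DataFrame, lfc_max: float = -1.0, fdr_max: float = 0.01
) -> set[str]:
    """Features with logFC strictly below ``lfc_max`` and FDR strictly
    below ``fdr_max`` (loss of occupancy upon pioneer-factor knockdown)."""
    sel = (diff["logFC"] < lfc_max) & (diff["fdr"] < fdr_max)
    return set(diff.index[sel])


# ---------------------------------------------------------------------------
# per-transcript occupancy counting

def transcript_counts_fpkm(
    fragments: FragmentSet,
    transcripts_df: pd.DataFrame,
    min_span: int = 125,
    min_sum: int = 10,
    stranded: bool = False,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Count fragments per transcript (multi-counted across isoforms) and FPKM.

    A fragment overlapping k transcripts contributes one count to each.
    Transcripts spanning fewer than ``min_span`` bp are dropped, as are
    transcripts whose total count across all samples is <= ``min_sum``
    (strictly more than ``min_sum`` required).  FPKM uses each sample's
    total fragment count as library size.
    """
    tdf = transcripts_df[(transcripts_df["end"] - transcripts_df["start"]) >= min_span]
    frame = fragments.frame
    samples = sorted(
        frame[["condition", "replicate"]].drop_duplicates().itertuples(index=False),
        key=tuple,
    )
    sample_ids = [f"{c}_{r}" for c, r in samples]
    counts = pd.DataFrame(0, index=tdf.index, columns=sample_ids, dtype=int)
    libsizes = {}
    for (condition, replicate), sid in zip(samples, sample_ids):
        sub = frame[(frame["condition"] == condition) & (frame["replicate"] == replicate)]
        libsizes[sid] = len(sub)
        for chrom, tchrom in tdf.groupby("chrom"):
            fsub = sub[sub["chrom"] == chrom]
            for strand_sel in ([None] if not stranded else ["+", "-"]):
                tgt = tchrom if strand_sel is None else tchrom[tchrom["strand"] == strand_sel]
                fs = fsub if strand_sel is None else fsub[fsub["strand"] == strand_sel]
                if not len(tgt) or not len(fs):
                    continue
                starts = np.sort(fs["start"].to_numpy())
                ends = np.sort(fs["end"].to_numpy())
                # overlap iff frag.start < t.end and frag.end > t.start
                n_start_lt = np.searchsorted(starts, tgt["end"].to_numpy(), side="left")
                n_end_le = np.searchsorted(ends, tgt["start"].to_numpy(), side="right")
                counts.loc[tgt.index, sid] += n_start_lt - n_end_le
    keep = counts.sum(axis=1) > min_sum
    counts = counts[keep]
    spans = (tdf["end"] - tdf["start"])[keep]
    meta = pd.DataFrame(
        {"condition": [c for c, _ in samples], "replicate": [r for _, r in samples]},
        index=sample_ids,
    )
    cm = CountMatrix(counts, meta, spans.rename("length"))
    lib = pd.Series(libsizes)
    fpkm = 1e9 * counts.div(lib, axis=1).div(spans, axis=0)
    return cm, fpkm


# ---------------------------------------------------------------------------
# quantitative ChIP scaling

def count_in_regions(fragments: FragmentSet, regions: pd.DataFrame) -> int:
    """Total fragments whose midpoint falls in any region (chrom/start/end)."""
    total = 0
    frame = fragments.frame
    mids = fragments.midpoints
    for chrom, sub in regions.groupby("chrom"):
        m = np.sort(mids[(frame["chrom"] == chrom).to_numpy()])
        if not len(m):
            continue
        lo = np.searchsorted(m, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(m, sub["end"].to_numpy(), side="left")
        total += int((hi - lo).sum())
    return total


def relacs_double_ratio(
    ip_kd: float, ip_ctrl: float, input_kd: float, input_ctrl: float,
    lib_ip_kd: float, lib_ip_ctrl: float, lib_input_kd: float, lib_input_ctrl: float,
) -> float:
    """Library-size-corrected double ratio of IP and input region counts.

    factor = [(IP_KD/L) / (IP_Ctrl/L)] / [(In_KD/L) / (In_Ctrl/L)];
    a factor below 1 means depletion in the knockdown.
    """
    for name, v in [("ip_ctrl", ip_ctrl), ("input_kd", input_kd),
                    ("input_ctrl", input_ctrl)]:
        if v == 0:
            raise ValueError(f"zero denominator component {name}")
    if lib_input_ctrl == 0 or lib_ip_kd == 0 or lib_ip_ctrl == 0 or lib_input_kd == 0:
        raise ValueError("zero library size")
    ip_ratio = (ip_kd / lib_ip_kd) / (ip_ctrl / lib_ip_ctrl)
    input_ratio = (input_kd / lib_input_kd) / (input_ctrl / lib_input_ctrl)
    return ip_ratio / input_ratio


def relacs_from_fragments(
    ip: FragmentSet, inputs: FragmentSet, regions: pd.DataFrame,
    kd: str = "DomKD", ctrl: str = "Ctrl",
) -> float:
    """Pooled-replicate double ratio over a region set.

    Library sizes are total fragments per condition (spike contigs
    included); region counts use fragment midpoints.
    """
    parts = {}
    for name, fs, condition in [
        ("ip_kd", ip, kd), ("ip_ctrl", ip, ctrl),
        ("input_kd", inputs, kd), ("input_ctrl", inputs, ctrl),
    ]:
        sub = fs.subset(condition=condition)
        parts[name] = (count_in_regions(sub, regions), len(sub))
    return relacs_double_ratio(
        parts["ip_kd"][0], parts["ip_ctrl"][0],
        parts["input_kd"][0], parts["input_ctrl"][0],
        parts["ip_kd"][1], parts["ip_ctrl"][1],
        parts["input_kd"][1], parts["input_ctrl"][1],
    )


# ---------------------------------------------------------------------------
# transforms and binning

def stabilized_log(
    cm: CountMatrix, size_factors: pd.Series, pseudocount: float = 1.0
) -> pd.DataFrame:
    """log2(count / size_factor + pseudocount), a variance-stabilizing
    shifted-log transform of size-factor-corrected counts."""
    sf = size_factors.reindex(cm.counts.columns)
    return np.log2(cm.counts.div(sf, axis=1) + pseudocount)


def replicate_mean(values: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns of the same condition."""
    cond = meta.loc[values.columns, "condition"]
    return values.T.groupby(cond.values).mean().T


def bin_counts(
    fragments: FragmentSet,
    bin_size: int = 500,
    min_mean: float = 25.0,
    include_spike: bool = False,
) -> CountMatrix:
    """Count fragment midpoints in genome-tiled bins per sample.

    Bins whose mean count across samples is <= ``min_mean`` are
    discarded (strictly greater required to keep).  Bin ids are
    ``chrom:start-end``.
    """
    build = fragments.build
    frame = fragments.frame
    chroms = build.names if include_spike else build.main_chromosomes
    samples = sorted(
        frame[["condition", "replicate"]].drop_duplicates().itertuples(index=False),
        key=tuple,
    )
    sample_ids = [f"{c}_{r}" for c, r in samples]
    index = []
    for chrom in chroms:
        n = -(-build.lengths[chrom] // bin_size)
        index += [f"{chrom}:{i * bin_size}-{min((i + 1) * bin_size, build.lengths[chrom])}"
                  for i in range(n)]
    counts = pd.DataFrame(0, index=index, columns=sample_ids, dtype=int)
    mids = fragments.midpoints
    for (condition, replicate), sid in zip(samples, sample_ids):
        sel = ((frame["condition"] == condition) & (frame["replicate"] == replicate)).to_numpy()
        for chrom in chroms:
            m = mids[sel & (frame["chrom"] == chrom).to_numpy()]
            if not len(m):
                continue
            n = -(-build.lengths[chrom] // bin_size)
            binned = np.bincount(m // bin_size, minlength=n)
            ids = [f"{chrom}:{i * bin_size}-{min((i + 1) * bin_size, build.lengths[chrom])}"
                   for i in range(n)]
            counts.loc[ids, sid] += binned
    keep = counts.mean(axis=1) > min_mean
    counts = counts[keep]
    meta = pd.DataFrame(
        {"condition": [c for c, _ in samples], "replicate": [r for _, r in samples]},
        index=sample_ids,
    )
    return CountMatrix(counts, meta)
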