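"""Statistics for IP mass-spectrometry enrichment.

Works from a log2 protein-intensity table with bait and control sample
groups: contaminant/decoy/site-only filtering, per-sample median
centering, shifted-normal imputation of missing-not-at-random values
(width 0.5, downshift 1.8 in units of each sample's observed sd), an
empirical-Bayes moderated t-test, Benjamini-Yekutieli correction, and
the final enrichment call (padj <= 0.05 and fold change of at least
50%, i.e. |log2FC| >= log2 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

FLAG_COLUMNS = ("contaminant", "decoy", "site_only")


@dataclass
class ProteinTable:
    """Log2 intensities (proteins x samples) with group labels and flags."""

    values: pd.DataFrame
    groups: pd.Series            # sample -> "bait" | "control"
    flags: pd.DataFrame          # protein x (contaminant, decoy, site_only)

    def __post_init__(self) -> None:
        if not set(self.groups.unique()) <= {"bait", "control"}:
            raise ValueError("groups must be 'bait' or 'control'")
        for g in ("bait", "control"):
            if (self.groups == g).sum() < 1:
                raise ValueError(f"no {g} samples")
        self.groups = self.groups.reindex(self.values.columns)
        self.flags = self.flags.reindex(self.values.index).fillna(False)

    def samples(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    @staticmethod
    def from_frame(table: pd.DataFrame, groups: dict[str, str] | None = None) -> "ProteinTable":
        """Build from a flat table whose flag columns sit beside samples.

        Group labels come from ``groups`` or, failing that, the frame's
        ``attrs["groups"]`` (as written by the synthetic generator) or a
        ``bait_*`` / ``ctrl_*`` column-name convention.
        """
        flags = pd.DataFrame(
            {c: table[c] if c in table.columns else False for c in FLAG_COLUMNS},
            index=table.index,
        ).astype(bool)
        sample_cols = [c for c in table.columns
                       if c not in FLAG_COLUMNS and table[c].dtype.kind == "f"]
        if groups is None:
            groups = table.attrs.get("groups") or {
                c: ("bait" if c.startswith("bait") else "control") for c in sample_cols
            }
        sample_cols = [c for c in sample_cols if c in groups]
        return ProteinTable(
            table[sample_cols].astype(float),
            pd.Series({c: groups[c] for c in sample_cols}),
            flags,
        )


def filter_proteins(table: ProteinTable, min_valid: int = 2) -> ProteinTable:
    """Drop flagged rows; keep rows with >= ``min_valid`` observed values
    in the bait group OR in the control group."""
    flagged = table.flags.any(axis=1)
    vals = table.values[~flagged]
    ok = pd.Series(False, index=vals.index)
    for g in ("bait", "control"):
        ok |= vals[table.samples(g)].notna().sum(axis=1) >= min_valid
    return ProteinTable(vals[ok], table.groups, table.flags.loc[vals.index[ok]])


def normalize_log(table: ProteinTable) -> ProteinTable:
    """Center each sample's observed log-intensities on the grand median."""
    grand = np.nanmedian(table.values.to_numpy())
    centered = table.values - table.values.median(axis=0) + grand
    return ProteinTable(centered, table.groups, table.flags)


def impute_shifted_normal(
    table: ProteinTable,
    width: float = 0.5,
    downshift: float = 1.8,
    seed: int | np.random.Generator = 0,
    per_sample: bool = True,
) -> ProteinTable:
    """Impute missing values from a down-shifted normal distribution.

    Missing entries of sample s are drawn from
    Normal(mu_s - downshift * sd_s, (width * sd_s)^2) where mu_s, sd_s
    are that sample's observed mean and sd (global moments when
    ``per_sample`` is off).  Observed values are never altered.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = table.values.copy()
    if not per_sample:
        mu_g = np.nanmean(vals.to_numpy())
        sd_g = np.nanstd(vals.to_numpy(), ddof=1)
    for col in vals.columns:
        x = vals[col]
        missing = x.isna()
        if not missing.any():
            continue
        if per_sample:
            if x.notna().sum() < 2:
                raise ValueError(f"sample {col} has fewer than 2 observed values")
            mu, sd = x.mean(), x.std(ddof=1)
        else:
            mu, sd = mu_g, sd_g
        vals.loc[missing, col] = rng.normal(mu - downshift * sd, width * sd,
                                            size=int(missing.sum()))
    return ProteinTable(vals, table.groups, table.flags)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (x > 0)."""
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def moderated_ttest(table: ProteinTable) -> pd.DataFrame:
    """Two-group moderated t-test with empirical-Bayes variance shrinkage.

    Per-protein pooled variance s^2 with d degrees of freedom is shrunk
    toward a prior s0^2 with d0 prior df: s~^2 = (d0 s0^2 + d s^2)/(d0+d).
    d0 and s0 come from matching the first two moments of log s^2 to the
    scaled-F model (d0 = inf when residual variances show no excess
    spread).  P-values use t with d0 + d df; padj is Benjamini-Yekutieli.
    """
    bait = table.samples("bait")
    ctrl = table.samples("control")
    xb = table.values[bait].to_numpy()
    xc = table.values[ctrl].to_numpy()
    if np.isnan(xb).any() or np.isnan(xc).any():
        raise ValueError("missing values present; impute first")
    n1, n2 = xb.shape[1], xc.shape[1]
    d = n1 + n2 - 2
    if d < 1:
        raise ValueError("not enough samples for a variance estimate")
    mb, mc = xb.mean(axis=1), xc.mean(axis=1)
    log2fc = mb - mc
    s2 = ((xb.var(axis=1, ddof=1) * (n1 - 1)) + (xc.var(axis=1, ddof=1) * (n2 - 1))) / d

    z = np.log(np.maximum(s2, 1e-300))
    e_z = z - digamma(d / 2.0) + np.log(d / 2.0)
    var_excess = np.var(z, ddof=1) - polygamma(1, d / 2.0)
    if var_excess > 0:
        d0 = 2.0 * _trigamma_inverse(var_excess)
        s0_2 = np.exp(np.mean(e_z) + digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(np.mean(e_z))
    if np.isinf(d0):
        s_tilde2 = np.full_like(s2, s0_2)
        df_total = 1e12  # effectively normal
    else:
        s_tilde2 = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    tstat = log2fc / np.sqrt(s_tilde2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=df_total)
    padj = multipletests(p, method="fdr_by")[1]
    return pd.DataFrame(
        {
            "log2FC": log2fc,
            "t": tstat,
            "p": p,
            "padj": padj,
            "s2": s2,
            "s2_moderated": s_tilde2,
        },
        index=table.values.index,
    )


def call_enriched(
    result: pd.DataFrame, padj_max: float = 0.05, fc_min: float = 1.5
) -> pd.DataFrame:
    """Flag proteins with padj <= ``padj_max`` and |log2FC| >= log2(fc_min)."""
    out = result.copy()
    sig = (out["padj"] <= padj_max) & (np.abs(out["log2FC"]) >= np.log2(fc_min))
    out["enriched"] = sig
    out["direction"] = np.where(out["log2FC"] >= 0, "up", "down")
    return out
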