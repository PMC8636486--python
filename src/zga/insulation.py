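"""Hi-C insulation scores, TAD boundaries and group profiles.

The insulation score of a bin is the multi-window mean of "diamond"
contact averages: for window w the diamond at bin i is the submatrix
[i-w, i-1] x [i+1, i+w] of the balanced matrix, i.e. contacts crossing
bin i.  Each per-window track is log2-normalized to its chromosome
mean (0 = average insulation, negative = more insulated) and the final
score averages the windows.  Boundaries are local minima whose score
drops below both flanking local maxima by at least a prominence delta.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .genome import ContactMatrix, FragmentSet, GenomeBuild


def bin_contacts(
    pairs: pd.DataFrame, build: GenomeBuild, bin_size: int = 2_000
) -> dict[str, ContactMatrix]:
    """Bin intra-chromosomal contact pairs into symmetric matrices.

    ``pairs`` needs columns chrom1, pos1, chrom2, pos2.  Inter-chromosomal
    pairs are discarded.
    """
    out = {}
    intra = pairs[pairs["chrom1"] == pairs["chrom2"]]
    for chrom in build.main_chromosomes:
        n = build.lengths[chrom] // bin_size
        mat = np.zeros((n, n))
        sub = intra[intra["chrom1"] == chrom]
        if len(sub):
            i = np.clip(sub["pos1"].to_numpy() // bin_size, 0, n - 1)
            j = np.clip(sub["pos2"].to_numpy() // bin_size, 0, n - 1)
            np.add.at(mat, (i, j), 1.0)
            np.add.at(mat, (j, i), 1.0)
            # a pair counted once per ordered direction; halve the diagonal
            d = np.arange(n)
            mat[d, d] /= 2.0
        out[chrom] = ContactMatrix(chrom, bin_size, mat)
    return out


def balance(matrix: ContactMatrix, tol: float = 1e-5, max_iter: int = 500) -> np.ndarray:
    """Iterative-correction balancing weights (equal row sums).

    Bins with zero marginal are masked (weight NaN).  Weights are scaled
    so covered balanced row sums average 1.  Raises on non-convergence.
    """
    M = matrix.matrix
    marg = M.sum(axis=1)
    mask = marg > 0
    if not mask.any():
        raise ValueError("matrix has no covered bins")
    b = np.ones(M.shape[0])
    cv = np.inf
    for _ in range(max_iter):
        s = (M * np.outer(b, b)).sum(axis=1)
        sc = s[mask]
        cv = sc.std() / sc.mean()
        if cv < tol:
            break
        rel = np.where(mask, s / sc.mean(), 1.0)
        rel[rel == 0] = 1.0
        b /= np.sqrt(rel)
    else:
        raise RuntimeError(f"balancing did not converge: row-sum CV {cv:.3g}")
    s = (M * np.outer(b, b)).sum(axis=1)[mask].mean()
    b = b / np.sqrt(s)
    weights = np.where(mask, b, np.nan)
    matrix.weights = weights
    return weights


def _diamond_means(balanced: np.ndarray, w: int) -> np.ndarray:
    """Mean of balanced[i-w:i, i+1:i+w+1] per bin i (NaN-aware)."""
    n = balanced.shape[0]
    vals = np.nan_to_num(balanced, nan=0.0)
    finite = np.isfinite(balanced).astype(float)
    # 2D prefix sums with a zero border
    S = np.zeros((n + 1, n + 1))
    S[1:, 1:] = np.cumsum(np.cumsum(vals, axis=0), axis=1)
    C = np.zeros((n + 1, n + 1))
    C[1:, 1:] = np.cumsum(np.cumsum(finite, axis=0), axis=1)

    def rect(P, r0, r1, c0, c1):
        return P[r1, c1] - P[r0, c1] - P[r1, c0] + P[r0, c0]

    out = np.full(n, np.nan)
    for i in range(w, n - w):
        r0, r1 = i - w, i          # rows [i-w, i-1]
        c0, c1 = i + 1, i + w + 1  # cols [i+1, i+w]
        cnt = rect(C, r0, r1, c0, c1)
        if cnt > 0:
            out[i] = rect(S, r0, r1, c0, c1) / cnt
    return out


def insulation_score(
    matrix: ContactMatrix,
    min_depth: int = 20_000,
    max_depth: int = 100_000,
    step: int = 2_000,
) -> pd.DataFrame:
    """Multi-window insulation track for one balanced chromosome.

    Depths are in bp and converted to bins; each window's diamond-mean
    track is log2-normalized by its chromosome mean over covered bins
    and the final score is the unweighted mean across windows.  Bins
    within the maximum window of a chromosome edge are uncovered (NaN
    score, covered flag False).
    """
    if matrix.weights is None:
        raise ValueError("balance the matrix first")
    bs = matrix.bin_size
    n = matrix.n_bins
    w_list = [d // bs for d in range(min_depth, max_depth + 1, step)]
    w_list = sorted({w for w in w_list if w >= 1})
    if not w_list:
        raise ValueError("no usable window depths")
    w_max = max(w_list)
    bal = matrix.balanced()
    if n < 2 * w_max + 1:
        score = np.full(n, np.nan)
        covered = np.zeros(n, dtype=bool)
    else:
        tracks = []
        for w in w_list:
            dm = _diamond_means(bal, w)
            with np.errstate(divide="ignore", invalid="ignore"):
                mean = np.nanmean(dm)
                tracks.append(np.log2(dm / mean))
        stackd = np.vstack(tracks)
        with np.errstate(invalid="ignore"):
            score = stackd.mean(axis=0)
        # -inf (a diamond with zero crossing contacts) is a measured
        # extreme, not missing data; only NaN means "no coverage"
        covered = ~np.isnan(score)
        covered[:w_max] = False
        covered[n - w_max:] = False
        score[~covered] = np.nan
        # masked bins propagate NaN through the diamond only when the
        # whole diamond is masked; a bin that is itself masked is uncovered
        masked = ~np.isfinite(matrix.weights)
        score[masked] = np.nan
        covered[masked] = False
    return pd.DataFrame(
        {
            "chrom": matrix.chrom,
            "start": np.arange(n) * bs,
            "end": np.minimum((np.arange(n) + 1) * bs, n * bs),
            "score": score,
            "covered": covered,
        }
    )


def call_boundaries(track: pd.DataFrame, delta: float = 0.01) -> pd.DataFrame:
    """Local insulation minima with prominence >= ``delta``.

    A boundary is a covered local minimum whose score lies below both
    the nearest flanking local maxima by at least ``delta``.  Plateaus
    resolve to their leftmost bin.
    """
    rows = []
    for chrom, sub in track.groupby("chrom", sort=False):
        s = sub["score"].to_numpy()
        idx = sub.index.to_numpy()
        finite = np.flatnonzero(np.isfinite(s))
        if len(finite) < 3:
            continue
        v = s[finite]
        # local extrema on the covered sub-track, plateau -> leftmost
        mins, maxs = [], []
        for k in range(len(v)):
            left = v[k - 1] if k > 0 else np.inf
            right = None
            kk = k
            while kk + 1 < len(v) and v[kk + 1] == v[k]:
                kk += 1
            if kk + 1 < len(v):
                right = v[kk + 1]
            if kk > k and k > 0 and left == v[k]:
                continue  # interior of plateau
            if right is None:
                continue
            if v[k] < left and v[k] < right:
                mins.append(k)
            if v[k] > left and v[k] > right:
                maxs.append(k)
        maxs_arr = np.array(maxs)
        for k in mins:
            lefts = maxs_arr[maxs_arr < k]
            rights = maxs_arr[maxs_arr > k]
            if not len(lefts) or not len(rights):
                continue
            prom = min(v[lefts[-1]] - v[k], v[rights[0]] - v[k])
            if prom >= delta:
                i = idx[finite[k]]
                rows.append((chrom, int(track.loc[i, "start"]) // _bin_size(track),
                             float(v[k]), float(prom)))
    return pd.DataFrame(rows, columns=["chrom", "bin", "score", "prominence"])


def _bin_size(track: pd.DataFrame) -> int:
    return int(track["end"].iloc[0] - track["start"].iloc[0])


def profile_over_groups(
    track: pd.DataFrame,
    tss_groups: dict[str, pd.DataFrame],
    flank: int = 20_000,
) -> dict[str, pd.DataFrame]:
    """Per-group pointwise median insulation profile around TSSs.

    Each TSS contributes its strand-oriented window of scores (minus
    strand reversed); uncovered bins are excluded pointwise.  Returns a
    frame per group with offset_bp, median and standard error.
    """
    bs = _bin_size(track)
    k = flank // bs
    by_chrom = {c: sub.reset_index(drop=True) for c, sub in track.groupby("chrom")}
    out = {}
    for name, tss_df in tss_groups.items():
        vectors = []
        for _, row in tss_df.iterrows():
            sub = by_chrom.get(row["chrom"])
            if sub is None:
                continue
            b = int(row["tss"]) // bs
            if b - k < 0 or b + k >= len(sub):
                continue
            vec = sub["score"].to_numpy()[b - k: b + k + 1]
            if row["strand"] == "-":
                vec = vec[::-1]
            vectors.append(vec)
        if not vectors:
            out[name] = pd.DataFrame(columns=["offset_bp", "median", "se", "n"])
            continue
        mat = np.vstack(vectors)
        n_fin = np.isfinite(mat).sum(axis=0)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(mat, axis=0)
            sd = np.nanstd(mat, axis=0, ddof=1)
        se = np.where(n_fin >= 2, sd / np.sqrt(np.maximum(n_fin, 1)), np.nan)
        out[name] = pd.DataFrame(
            {
                "offset_bp": (np.arange(-k, k + 1)) * bs,
                "median": med,
                "se": se,
                "n": n_fin,
            }
        )
    return out


def boundary_distance(
    tss_df: pd.DataFrame, boundaries: pd.DataFrame, bin_size: int
) -> pd.Series:
    """Unsigned distance (bp) from each TSS to the nearest boundary bin
    center on its chromosome; NaN when the chromosome has none."""
    out = pd.Series(np.nan, index=tss_df.index)
    for chrom, sub in tss_df.groupby("chrom"):
        b = boundaries[boundaries["chrom"] == chrom]["bin"].to_numpy()
        if not len(b):
            continue
        centers = b * bin_size + bin_size / 2.0
        d = np.abs(sub["tss"].to_numpy()[:, None] - centers[None, :]).min(axis=1)
        out.loc[sub.index] = d
    return out


def insulation_difference(track_a: pd.DataFrame, track_b: pd.DataFrame) -> pd.DataFrame:
    """a - b per bin where both tracks are covered; NaN elsewhere."""
    if not (track_a[["chrom", "start", "end"]].reset_index(drop=True)
            .equals(track_b[["chrom", "start", "end"]].reset_index(drop=True))):
        raise ValueError("tracks are not on the same bins")
    out = track_a[["chrom", "start", "end"]].copy()
    a = track_a["score"].to_numpy()
    b = track_b["score"].to_numpy()
    both = np.isfinite(a) & np.isfinite(b)
    diff = np.where(both, a - b, np.nan)
    out["score"] = diff
    out["covered"] = both
    return out
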