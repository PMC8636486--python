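"""Readers and writers for the plain-text formats the pipeline touches.

External conventions
--------------------
GTF           1-based closed; converted to 0-based half-open on load.
BED6          0-based half-open; optional 7th column carries a q-value.
bedGraph      0-based half-open, disjoint intervals required on read.
count TSV     first column = feature id, remaining columns = samples;
              sample metadata in a sibling TSV (sample, condition, replicate).
fragment TSV  chrom, start, end, strand, assay, condition, replicate.
contact text  ``#bin_size=<int>`` header then chrom, bin_i, bin_j, count
              triplets with bin_i <= bin_j; symmetrized on load.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import (
    FRAGMENT_COLUMNS,
    ContactMatrix,
    CountMatrix,
    FragmentSet,
    GenomeBuild,
    Interval,
    TranscriptUnit,
)

log = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def load_annotation(
    path, build: GenomeBuild, protein_coding_only: bool = True
) -> list[TranscriptUnit]:
    """Load transcript records from a GTF file.

    Coordinates are converted from the GTF's 1-based closed convention
    to 0-based half-open.  When a ``transcript_biotype`` (or
    ``gene_biotype``) attribute is present and ``protein_coding_only``
    is set, only protein-coding transcripts are retained.  Records on
    chromosomes missing from ``build`` are skipped with a warning.
    """
    out: list[TranscriptUnit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "transcript":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            if chrom not in build:
                log.warning("%s:%d: unknown chromosome %r, record skipped", path, lineno, chrom)
                continue
            attr = dict(_ATTR_RE.findall(attrs))
            biotype = attr.get("transcript_biotype", attr.get("gene_biotype"))
            if protein_coding_only and biotype is not None and biotype != "protein_coding":
                continue
            tid = attr.get("transcript_id")
            gid = attr.get("gene_id", tid)
            if tid is None:
                raise ValueError(f"{path}:{lineno}: transcript without transcript_id")
            out.append(
                TranscriptUnit(
                    transcript_id=tid,
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    start=start_i - 1,
                    end=end_i,
                )
            )
    return out


def write_annotation(path, transcripts: Iterable[TranscriptUnit]) -> None:
    """Write transcripts as minimal GTF (inverse of :func:`load_annotation`)."""
    with open(path, "w") as fh:
        for t in transcripts:
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "protein_coding";'
            )
            fh.write(
                f"{t.chrom}\tzga\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs}\n"
            )


def read_bed(path) -> list[Interval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: empty interval")
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 and f[5] in "+-" else None
            qvalue = float(f[6]) if len(f) > 6 and f[6] != "." else None
            out.append(Interval(chrom, start, end, strand=strand, score=score, qvalue=qvalue))
    return out


def write_bed(path, intervals: Iterable[Interval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:.6g}"
            strand = iv.strand if iv.strand is not None else "."
            cols = [iv.chrom, str(iv.start), str(iv.end), ".", score, strand]
            if iv.qvalue is not None:
                cols.append(f"{iv.qvalue:.6g}")
            fh.write("\t".join(cols) + "\n")


def read_bedgraph(path) -> pd.DataFrame:
    """Read a bedGraph track; overlapping intervals are an error."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
    )
    for _chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        if (grp["end"].to_numpy()[:-1] > grp["start"].to_numpy()[1:]).any():
            raise ValueError(f"{path}: overlapping bedGraph intervals on {_chrom}")
    return df


def write_bedgraph(path, track: pd.DataFrame, merge_equal: bool = False) -> None:
    """Write a (chrom, start, end, value) frame; NaN rows are skipped."""
    track = track.dropna(subset=["value"])
    with open(path, "w") as fh:
        prev = None
        for row in track.itertuples(index=False):
            cur = [row.chrom, int(row.start), int(row.end), float(row.value)]
            if (
                merge_equal
                and prev is not None
                and prev[0] == cur[0]
                and prev[2] == cur[1]
                and prev[3] == cur[3]
            ):
                prev[2] = cur[2]
                continue
            if prev is not None:
                fh.write(f"{prev[0]}\t{prev[1]}\t{prev[2]}\t{prev[3]:.6f}\n")
            prev = cur
        if prev is not None:
            fh.write(f"{prev[0]}\t{prev[1]}\t{prev[2]}\t{prev[3]:.6f}\n")


def read_fragments(path, build: GenomeBuild) -> FragmentSet:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "replicate": str})
    return FragmentSet(df, build)


def write_fragments(path, fragments: FragmentSet) -> None:
    fragments.frame.to_csv(path, sep="\t", index=False)


def read_counts(path, meta_path, lengths_path=None) -> CountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype={"replicate": str})
    lengths = None
    if lengths_path is not None:
        lengths = pd.read_csv(lengths_path, sep="\t", index_col=0).iloc[:, 0]
    return CountMatrix(counts, meta, lengths)


def write_counts(path, meta_path, cm: CountMatrix, lengths_path=None) -> None:
    cm.counts.to_csv(path, sep="\t")
    cm.meta.to_csv(meta_path, sep="\t")
    if lengths_path is not None and cm.lengths is not None:
        cm.lengths.rename("length").to_csv(lengths_path, sep="\t")


def read_contacts(path, build: GenomeBuild | None = None) -> dict[str, ContactMatrix]:
    """Load chrom/bin_i/bin_j/count triplets into dense symmetric matrices."""
    bin_size = None
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*bin_size\s*=\s*(\d+)", line)
                if m:
                    bin_size = int(m.group(1))
                continue
            f = line.split("\t")
            chrom, i, j, c = f[0], int(f[1]), int(f[2]), float(f[3])
            if c < 0:
                raise ValueError(f"{path}:{lineno}: negative contact count")
            rows.append((chrom, min(i, j), max(i, j), c))
    if bin_size is None:
        raise ValueError(f"{path}: missing '#bin_size=<int>' header")
    df = pd.DataFrame(rows, columns=["chrom", "i", "j", "count"])
    dup = df.groupby(["chrom", "i", "j"])["count"].nunique()
    if (dup > 1).any():
        raise ValueError(f"{path}: conflicting duplicate triplets")
    df = df.drop_duplicates(["chrom", "i", "j"])
    out: dict[str, ContactMatrix] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        if build is not None:
            n = -(-build.lengths[chrom] // bin_size)
            if int(grp[["i", "j"]].to_numpy().max()) >= n:
                raise ValueError(f"{path}: bin beyond end of {chrom}")
        else:
            n = int(grp[["i", "j"]].to_numpy().max()) + 1
        mat = np.zeros((n, n))
        ii = grp["i"].to_numpy()
        jj = grp["j"].to_numpy()
        mat[ii, jj] = grp["count"].to_numpy()
        mat[jj, ii] = grp["count"].to_numpy()
        out[chrom] = ContactMatrix(chrom, bin_size, mat)
    return out


def write_contacts(path, matrices: dict[str, ContactMatrix]) -> None:
    sizes = {m.bin_size for m in matrices.values()}
    if len(sizes) != 1:
        raise ValueError("all matrices must share one bin_size")
    with open(path, "w") as fh:
        fh.write(f"#bin_size={sizes.pop()}\n")
        for chrom, m in matrices.items():
            iu, ju = np.triu_indices(m.n_bins)
            vals = m.matrix[iu, ju]
            keep = vals != 0
            for i, j, c in zip(iu[keep], ju[keep], vals[keep]):
                fh.write(f"{chrom}\t{i}\t{j}\t{c:.6g}\n")
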