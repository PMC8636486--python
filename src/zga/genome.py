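"""Shared domain types and coordinate conventions.

All coordinates are 0-based half-open.  "Downstream" always means
increasing signed offset along a transcript's strand:

    offset(p) = p - tss          for '+' transcripts
    offset(p) = tss - p          for '-' transcripts

so that a +1 nucleosome has a positive offset and a -1 nucleosome a
negative offset on either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-")

FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand", "assay", "condition", "replicate"]


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes, optionally with spike-in contigs.

    Spike-in contigs (e.g. an exogenous phage genome mixed into a
    chromatin profiling library at a known share) take part in fragment
    bookkeeping but are excluded from biological analyses.
    """

    chromosomes: tuple[tuple[str, int], ...]
    spike_contigs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for n, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {n!r} has non-positive length")
        unknown = set(self.spike_contigs) - set(names)
        if unknown:
            raise ValueError(f"spike contigs not in build: {sorted(unknown)}")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def main_chromosomes(self) -> list[str]:
        """Chromosome names that are not spike-in contigs."""
        return [n for n, _ in self.chromosomes if n not in self.spike_contigs]

    def __contains__(self, name: str) -> bool:
        return name in self.lengths


def tss_of(start: int, end: int, strand: str) -> int:
    """Transcription start of a 0-based half-open span on a given strand."""
    if strand == "+":
        return start
    if strand == "-":
        return end - 1
    raise ValueError(f"bad strand {strand!r}")


def signed_offset(pos, tss, strand):
    """Strand-aware offset of ``pos`` relative to ``tss`` (bp downstream)."""
    pos = np.asarray(pos)
    if strand == "+":
        return pos - tss
    if strand == "-":
        return tss - pos
    raise ValueError(f"bad strand {strand!r}")


@dataclass(frozen=True)
class TranscriptUnit:
    """A transcription unit with a strand-aware TSS."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(
                f"{self.transcript_id}: start {self.start} >= end {self.end}"
            )

    @property
    def tss(self) -> int:
        return tss_of(self.start, self.end, self.strand)

    @property
    def span(self) -> int:
        return self.end - self.start

    def offset(self, pos):
        return signed_offset(pos, self.tss, self.strand)


def transcripts_frame(transcripts: Iterable[TranscriptUnit]) -> pd.DataFrame:
    """Tabulate transcripts, one row per unit, with a derived ``tss`` column."""
    rows = [
        (t.transcript_id, t.gene_id, t.chrom, t.strand, t.start, t.end, t.tss)
        for t in transcripts
    ]
    return pd.DataFrame(
        rows,
        columns=["transcript_id", "gene_id", "chrom", "strand", "start", "end", "tss"],
    ).set_index("transcript_id")


@dataclass(frozen=True)
class Interval:
    chrom: str
    start: int
    end: int
    strand: str | None = None
    score: float | None = None
    qvalue: float | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")
        if self.qvalue is not None and not 0.0 <= self.qvalue <= 1.0:
            raise ValueError(f"qvalue {self.qvalue} outside [0, 1]")


class FragmentSet:
    """Strand-aware aligned fragments tagged by assay/condition/replicate.

    Thin wrapper over a DataFrame with columns
    ``chrom, start, end, strand, assay, condition, replicate``.
    """

    def __init__(self, frame: pd.DataFrame, build: GenomeBuild):
        missing = [c for c in FRAGMENT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"fragment frame missing columns {missing}")
        frame = frame[FRAGMENT_COLUMNS].reset_index(drop=True)
        bad_chrom = set(frame["chrom"].unique()) - set(build.names)
        if bad_chrom:
            raise ValueError(f"fragments on unknown chromosomes: {sorted(bad_chrom)}")
        if (frame["start"] >= frame["end"]).any():
            raise ValueError("fragments with start >= end")
        self.frame = frame
        self.build = build

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, **key: str) -> "FragmentSet":
        """Select fragments by equality on any tag column (assay, condition, ...)."""
        mask = pd.Series(True, index=self.frame.index)
        for col, value in key.items():
            mask &= self.frame[col] == value
        return FragmentSet(self.frame[mask], self.build)

    @property
    def lengths(self) -> np.ndarray:
        return (self.frame["end"] - self.frame["start"]).to_numpy()

    @property
    def midpoints(self) -> np.ndarray:
        return ((self.frame["start"] + self.frame["end"]) // 2).to_numpy()

    def five_prime(self) -> np.ndarray:
        """Per-fragment 5' end (strand-aware, 0-based position)."""
        plus = self.frame["strand"].to_numpy() == "+"
        return np.where(plus, self.frame["start"], self.frame["end"] - 1)

    @staticmethod
    def concat(parts: Sequence["FragmentSet"]) -> "FragmentSet":
        if not parts:
            raise ValueError("nothing to concatenate")
        build = parts[0].build
        return FragmentSet(pd.concat([p.frame for p in parts], ignore_index=True), build)


class CountMatrix:
    """Features x samples integer counts plus per-sample metadata."""

    def __init__(
        self,
        counts: pd.DataFrame,
        meta: pd.DataFrame,
        lengths: pd.Series | None = None,
    ):
        if (counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        missing = set(counts.columns) - set(meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        for col in ("condition", "replicate"):
            if col not in meta.columns:
                raise ValueError(f"meta missing column {col!r}")
        self.counts = counts
        self.meta = meta.loc[list(counts.columns)]
        if lengths is not None:
            lengths = lengths.reindex(counts.index)
            if lengths.isna().any():
                raise ValueError("feature lengths incomplete")
        self.lengths = lengths

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        return list(self.meta.index[self.meta["condition"] == condition])

    def subset_features(self, features: Sequence[str]) -> "CountMatrix":
        lengths = self.lengths.loc[list(features)] if self.lengths is not None else None
        return CountMatrix(self.counts.loc[list(features)], self.meta, lengths)


class ContactMatrix:
    """Per-chromosome binned symmetric contact counts.

    ``matrix`` is dense (n_bins x n_bins); ``weights`` are optional
    multiplicative balancing weights with NaN at masked bins.
    """

    def __init__(
        self,
        chrom: str,
        bin_size: int,
        matrix: np.ndarray,
        weights: np.ndarray | None = None,
    ):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
            raise ValueError("contact matrix must be square")
        if not np.allclose(matrix, matrix.T):
            raise ValueError("contact matrix must be symmetric")
        self.chrom = chrom
        self.bin_size = bin_size
        self.matrix = matrix
        if weights is not None:
            weights = np.asarray(weights, dtype=float)
            if weights.shape != (matrix.shape[0],):
                raise ValueError("weights shape mismatch")
        self.weights = weights

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def balanced(self) -> np.ndarray:
        """Weight-corrected matrix with NaN on masked rows/columns."""
        if self.weights is None:
            raise ValueError("matrix has no balancing weights")
        w = self.weights
        return self.matrix * np.outer(w, w)

    def bin_of(self, pos: int) -> int:
        return int(pos // self.bin_size)
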