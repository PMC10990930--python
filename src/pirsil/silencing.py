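"""Silencing-signature quantification.

Epigenetic repression of a piRNA target leaves a quantitative footprint:
antisense 22G-RNA (and, in the repressed state, 26G-RNA) accumulation over
the target transcript, and — where chromatin marks are involved — an
enrichment of ChIP coverage over input. This module computes per-position
antisense coverage tracks (per million 22G reads of the library),
per-transcript class abundances (tpm = reads per million class-total
reads), licensed-vs-repressed fold changes with an unpaired t-test, and
library-size-normalized ChIP/input ratio tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import Library
from .stats import unpaired_t_test

__all__ = [
    "CoverageTrack",
    "AbundanceRecord",
    "FoldChangeResult",
    "Transcript",
    "antisense_coverage",
    "class_abundance",
    "fold_change_test",
    "chip_input_ratio",
]


@dataclass(frozen=True)
class Transcript:
    """A mature transcript modeled as one genomic interval (0-based
    half-open) with a strand; position 0 of the transcript is its 5' end."""

    transcript_id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CoverageTrack:
    reference: str
    values: np.ndarray
    norm: str                 # "raw" | "per-million-22G" | "cpm" | "ratio"
    library_size: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass(frozen=True)
class AbundanceRecord:
    transcript_id: str
    read_class: str           # "s22G" | "s26G"
    count: int
    tpm: float
    library: str


@dataclass(frozen=True)
class FoldChangeResult:
    mean_a: float
    mean_b: float
    fold: float               # mean_b / mean_a
    log2_fold: float
    t: float
    df: float
    p_value: float


def _antisense_reads(lib: Library, transcript: Transcript, read_class: str) -> pd.DataFrame:
    df = lib.reads
    anti = "-" if transcript.strand == "+" else "+"
    keep = (
        (df.read_class == read_class)
        & (df.nhits > 0)
        & (df.chrom == transcript.chrom)
        & (df.strand == anti)
        & (df.start < transcript.end)
        & (df.end > transcript.start)
    )
    return df.loc[keep]


def antisense_coverage(
    lib: Library,
    transcript: Transcript,
    read_class: str = "s22G",
    norm: str = "per-million-22G",
) -> CoverageTrack:
    """Per-position depth of antisense reads of a class over the mature
    transcript, scaled per million total 22G reads of the library.
    Transcript coordinates run 5' to 3'."""
    reads = _antisense_reads(lib, transcript, read_class)
    values = np.zeros(transcript.length)
    for s, e, c in zip(reads.start, reads.end, reads["count"]):
        lo = max(0, int(s) - transcript.start)
        hi = min(transcript.length, int(e) - transcript.start)
        values[lo:hi] += c
    if transcript.strand == "-":
        values = values[::-1]
    if norm == "per-million-22G":
        if lib.total_22g == 0:
            raise ValueError(f"library {lib.name!r} has zero 22G reads")
        values = values / lib.total_22g * 1e6
        size = lib.total_22g
    elif norm == "raw":
        size = lib.total_22g
    else:
        raise ValueError(f"unknown normalization {norm!r}")
    return CoverageTrack(reference=transcript.transcript_id, values=values,
                         norm=norm, library_size=size)


def class_abundance(lib: Library, transcript: Transcript,
                    read_class: str = "s22G") -> AbundanceRecord:
    """Antisense reads of one class overlapping the transcript, counted once
    each, in tpm (per million class-total reads of the library)."""
    class_total = {"s22G": lib.total_22g, "s26G": lib.total_26g}[read_class]
    if class_total == 0:
        raise ValueError(
            f"library {lib.name!r} has zero mapped {read_class} reads")
    reads = _antisense_reads(lib, transcript, read_class)
    count = int(reads["count"].sum())
    return AbundanceRecord(
        transcript_id=transcript.transcript_id,
        read_class=read_class,
        count=count,
        tpm=count / class_total * 1e6,
        library=lib.name,
    )


def fold_change_test(
    state_a: list[AbundanceRecord],
    state_b: list[AbundanceRecord],
    welch: bool = False,
    log_scale: bool = False,
) -> FoldChangeResult:
    """Fold change of mean abundance between two states (b over a) with a
    two-sided unpaired t-test on the replicate tpm values (Student by
    default; optionally on log2 tpm)."""
    if len(state_a) < 2 or len(state_b) < 2:
        raise ValueError("need at least two replicates per state")
    a = np.array([r.tpm for r in state_a], dtype=float)
    b = np.array([r.tpm for r in state_b], dtype=float)
    if log_scale:
        t, df, p = unpaired_t_test(np.log2(a), np.log2(b), welch=welch)
    else:
        t, df, p = unpaired_t_test(a, b, welch=welch)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    fold = mean_b / mean_a if mean_a > 0 else float("inf")
    return FoldChangeResult(
        mean_a=mean_a,
        mean_b=mean_b,
        fold=fold,
        log2_fold=float(np.log2(fold)) if fold > 0 and np.isfinite(fold) else float("nan"),
        t=t,
        df=df,
        p_value=p,
    )


def chip_input_ratio(chip: CoverageTrack, input_: CoverageTrack,
                     pseudocount: float = 0.5) -> CoverageTrack:
    """Position-wise ChIP/input ratio after scaling both tracks to counts
    per million of their own library sizes; a pseudocount (cpm units)
    stabilizes uncovered positions."""
    if len(chip.values) != len(input_.values):
        raise ValueError("ChIP and input tracks differ in length")
    if chip.library_size <= 0 or input_.library_size <= 0:
        raise ValueError("library sizes must be positive")
    chip_cpm = chip.values / chip.library_size * 1e6
    input_cpm = input_.values / input_.library_size * 1e6
    ratio = (chip_cpm + pseudocount) / (input_cpm + pseudocount)
    return CoverageTrack(reference=chip.reference, values=ratio,
                         norm="ratio", library_size=chip.library_size)
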