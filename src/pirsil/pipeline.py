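"""Turning raw reads into a processed small-RNA library.

A :class:`Library` is the unit every downstream analysis consumes: unique
read sequences with their multiplicities, length/5'-base class, perfect
mapping result (all-occurrence count plus the primary hit) and genomic
context, together with the library-size denominators used for
normalization. Duplicate reads are collapsed before mapping, which makes
million-read libraries cheap to process without changing any count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .srna import GenomeIndex, annotate_table, classify_sequences, trim_adapter

__all__ = ["Library", "process_library", "reads_to_counts"]


@dataclass
class Library:
    name: str
    reads: pd.DataFrame          # seq count length class nhits chrom start end strand context
    genome_id: str
    total_reads: int = 0         # all reads entering mapping
    total_mapped: int = 0        # reads with >= 1 perfect hit
    total_mirna: int = 0         # mapped reads in miRNA context
    total_22g: int = 0           # mapped reads of class s22G
    total_26g: int = 0
    meta: dict = field(default_factory=dict)


def reads_to_counts(seqs) -> pd.DataFrame:
    """Collapse an iterable of read sequences to a (seq, count) table."""
    s = pd.Series(list(seqs), dtype=object)
    vc = s.value_counts()
    return pd.DataFrame({"seq": vc.index, "count": vc.values})


def process_library(
    read_counts: pd.DataFrame,
    index: GenomeIndex,
    features: pd.DataFrame,
    name: str = "lib",
    genome_id: str = "genome",
    adapter: str | None = None,
    min_overlap: int = 3,
    min_length: int = 18,
    meta: dict | None = None,
) -> Library:
    """Classify, perfectly map and annotate a collapsed read table.

    When `adapter` is given, reads are 3'-adapter-trimmed first and reads
    falling below `min_length` are discarded. Multimapping reads keep their
    first hit (coordinate order) as primary but are flagged by `nhits`.
    """
    df = read_counts.copy()
    if adapter is not None:
        trimmed = df.seq.map(lambda s: trim_adapter(s, adapter, min_overlap, min_length))
        df = df[trimmed.notna()].copy()
        df["seq"] = trimmed[trimmed.notna()]
        df = df.groupby("seq", as_index=False)["count"].sum()
    df = df.reset_index(drop=True)
    df["length"] = df.seq.str.len()
    df["read_class"] = classify_sequences(df.seq)

    nhits = np.zeros(len(df), dtype=np.int32)
    chrom = np.empty(len(df), dtype=object)
    start = np.full(len(df), -1, dtype=np.int64)
    strand = np.empty(len(df), dtype=object)
    for i, seq in enumerate(df.seq):
        hits = index.map_perfect(seq)
        nhits[i] = len(hits)
        if hits:
            chrom[i], start[i], strand[i] = hits[0].chrom, hits[0].start, hits[0].strand
    df["nhits"] = nhits
    df["chrom"] = chrom
    df["start"] = start
    df["end"] = start + df.length
    df["strand"] = strand

    mapped = df.nhits > 0
    df["context"] = "unmapped"
    if mapped.any():
        df.loc[mapped, "context"] = annotate_table(df.loc[mapped], features)

    total_reads = int(df["count"].sum())
    total_mapped = int(df.loc[mapped, "count"].sum())
    total_mirna = int(df.loc[mapped & (df.context == "miRNA"), "count"].sum())
    total_22g = int(df.loc[mapped & (df.read_class == "s22G"), "count"].sum())
    total_26g = int(df.loc[mapped & (df.read_class == "s26G"), "count"].sum())
    return Library(
        name=name,
        reads=df,
        genome_id=genome_id,
        total_reads=total_reads,
        total_mapped=total_mapped,
        total_mirna=total_mirna,
        total_22g=total_22g,
        total_26g=total_26g,
        meta=meta or {},
    )
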