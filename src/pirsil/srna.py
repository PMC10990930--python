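"""Small-RNA read processing: adapter trimming, length/5'-base
classification, perfect mapping, genomic-context annotation and
library-size normalization.

Read classes follow the nematode small-RNA nomenclature: 21U (21 nt, 5'
uridine — piRNA candidates), 22G and 26G (22/26 nt, 5' guanosine —
secondary/surveillance siRNAs antisense to their targets), miRNA (resolved
by mapping to annotated miRNA loci), and "other". Only perfect, full-length
genome matches count as mapped; a read with any mismatch, or containing N,
simply does not map.

Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
converted at the I/O boundary.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .util import check_alphabet, revcomp

__all__ = [
    "MappedRead",
    "GenomeIndex",
    "CountTable",
    "trim_adapter",
    "classify_read",
    "map_perfect",
    "annotate_context",
    "annotate_table",
    "normalize",
    "classify_sequences",
]

CONTEXT_PRECEDENCE = ["rRNA", "tRNA", "miRNA", "CDS"]


@dataclass(frozen=True)
class MappedRead:
    chrom: str
    start: int          # 0-based leftmost genome coordinate of the match
    strand: str         # '+' or '-'
    length: int
    context: str = "unannotated"


def trim_adapter(seq: str, adapter: str, min_overlap: int = 3,
                 min_length: int = 18) -> str | None:
    """Remove the longest read suffix equal to a prefix of the 3' adapter
    (at least `min_overlap` long). Returns the trimmed read, the unchanged
    read when no adapter is found, or None when the trimmed read is shorter
    than `min_length`."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    for size in range(min(len(seq), len(adapter)), min_overlap - 1, -1):
        if seq.endswith(adapter[:size]):
            seq = seq[:-size]
            break
    return seq if len(seq) >= min_length else None


def classify_read(seq: str) -> str:
    """Length/5'-base read class: p21U, s22G, s26G or other. miRNA status is
    assigned later, from mapping context."""
    n = len(seq)
    if n == 21 and seq[:1] == "T":
        return "p21U"
    if n == 22 and seq[:1] == "G":
        return "s22G"
    if n == 26 and seq[:1] == "G":
        return "s26G"
    return "other"


def classify_sequences(seqs: pd.Series) -> pd.Series:
    """Vectorized classify_read over a Series of sequences."""
    lengths = seqs.str.len()
    first = seqs.str[0]
    out = pd.Series("other", index=seqs.index, dtype=object)
    out[(lengths == 21) & (first == "T")] = "p21U"
    out[(lengths == 22) & (first == "G")] = "s22G"
    out[(lengths == 26) & (first == "G")] = "s26G"
    return out


class GenomeIndex:
    """Exact-occurrence index over a set of chromosomes.

    Anchored on a k-mer dictionary of the plus strand: a candidate position
    is reported only after full-length string verification, so hits are
    exactly the perfect full-length matches. Reads shorter than the anchor
    fall back to a naive scan.
    """

    def __init__(self, sequences: dict[str, str], k: int = 12):
        self.sequences = dict(sequences)
        self.k = k
        self._anchors: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in self.sequences.items():
            for pos in range(len(seq) - k + 1):
                self._anchors[seq[pos:pos + k]].append((chrom, pos))

    def _find_plus(self, seq: str) -> list[tuple[str, int]]:
        n = len(seq)
        if "N" in seq:
            return []
        if n >= self.k:
            hits = []
            for chrom, pos in self._anchors.get(seq[: self.k], ()):
                if self.sequences[chrom][pos:pos + n] == seq:
                    hits.append((chrom, pos))
            return hits
        hits = []
        for chrom, ref in self.sequences.items():
            start = ref.find(seq)
            while start != -1:
                hits.append((chrom, start))
                start = ref.find(seq, start + 1)
        return hits

    def map_perfect(self, seq: str) -> list[MappedRead]:
        """All exact full-length occurrences on both strands. The start of a
        minus-strand hit is the leftmost genome coordinate of the match."""
        check_alphabet(seq, "ACGTN", "read")
        n = len(seq)
        out = [MappedRead(c, p, "+", n) for c, p in self._find_plus(seq)]
        rc = revcomp(seq)
        out += [MappedRead(c, p, "-", n) for c, p in self._find_plus(rc)]
        out.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return out


def map_perfect(seq: str, genome: "GenomeIndex | dict[str, str]") -> list[MappedRead]:
    if isinstance(genome, dict):
        genome = GenomeIndex(genome)
    return genome.map_perfect(seq)


def annotate_context(chrom: str, start: int, end: int, strand: str,
                     features: pd.DataFrame) -> str:
    """Genomic context of one mapped interval with precedence
    rRNA > tRNA > miRNA > CDS > intergenic. CDS context carries relative
    orientation: CDS-antisense when the hit strand opposes the CDS strand.

    `features` uses 0-based half-open coordinates with columns
    type/chrom/start/end/strand.
    """
    sub = features[(features.chrom == chrom)
                   & (features.start < end) & (features.end > start)]
    for ftype in CONTEXT_PRECEDENCE:
        rows = sub[sub.type == ftype]
        if len(rows) == 0:
            continue
        if ftype != "CDS":
            return ftype
        sense = (rows.strand == strand).any()
        return "CDS-sense" if sense else "CDS-antisense"
    return "intergenic"


def annotate_table(hits: pd.DataFrame, features: pd.DataFrame) -> pd.Series:
    """Vectorized context annotation for a table of mapped reads (columns
    chrom/start/end/strand), applying the same precedence as
    :func:`annotate_context`."""
    context = pd.Series("intergenic", index=hits.index, dtype=object)
    assigned = pd.Series(False, index=hits.index)
    for ftype in CONTEXT_PRECEDENCE:
        frows = features[features.type == ftype]
        if len(frows) == 0:
            continue
        for chrom, chrom_feats in frows.groupby("chrom"):
            sel = (hits.chrom == chrom) & ~assigned
            if not sel.any():
                continue
            sub = hits.loc[sel]
            any_ov = pd.Series(False, index=sub.index)
            sense_ov = pd.Series(False, index=sub.index)
            for _, f in chrom_feats.iterrows():
                ov = (sub.start < f.end) & (sub.end > f.start)
                if not ov.any():
                    continue
                any_ov |= ov
                if ftype == "CDS":
                    sense_ov |= ov & (sub.strand == f.strand)
            idx = sub.index[any_ov]
            if len(idx) == 0:
                continue
            if ftype == "CDS":
                context.loc[sub.index[any_ov & sense_ov]] = "CDS-sense"
                context.loc[sub.index[any_ov & ~sense_ov]] = "CDS-antisense"
            else:
                context.loc[idx] = ftype
            assigned.loc[idx] = True
    return context


@dataclass
class CountTable:
    """Per-entity raw counts per library plus the denominators needed for
    normalization."""

    counts: pd.DataFrame                    # entities x libraries, raw counts
    total_mapped: dict[str, float]          # per-library mapped-read totals
    total_mirna: dict[str, float] = field(default_factory=dict)
    total_22g: dict[str, float] = field(default_factory=dict)
    mode: str = "raw"


def normalize(table: CountTable, mode: str) -> CountTable:
    """Scale raw counts to parts-per-million of the chosen denominator:

    * ``ppm_total`` — per million genome-mapped reads of the library;
    * ``per_miRNA`` — per million miRNA-mapped reads;
    * ``per_class_22G`` — per million 22G-class reads.
    """
    denominators = {
        "ppm_total": table.total_mapped,
        "per_miRNA": table.total_mirna,
        "per_class_22G": table.total_22g,
    }
    if mode not in denominators:
        raise ValueError(f"unknown normalization mode {mode!r}")
    denom = denominators[mode]
    out = table.counts.astype(float).copy()
    for lib in out.columns:
        d = denom.get(lib, 0)
        if not d or d <= 0:
            raise ValueError(
                f"library {lib!r} has a zero denominator for mode {mode!r}")
        out[lib] = out[lib] / d * 1e6
    return CountTable(
        counts=out,
        total_mapped=table.total_mapped,
        total_mirna=table.total_mirna,
        total_22g=table.total_22g,
        mode=mode,
    )
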