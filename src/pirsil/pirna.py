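"""piRNA (21U-RNA) locus annotation.

A piRNA locus is a distinct (chromosome, start, strand) 21-bp footprint
supported by uniquely and perfectly mapping 21U reads that do not fall in
coding sequence, tRNA or rRNA context. Loci are retained when their mean
abundance across libraries reaches a ppm threshold (default 0.1 ppm of all
genome-mapped reads, inclusive), and reported with their genomic
distribution — in Caenorhabditis the bulk of piRNA loci sit in clusters on
a single chromosome.
"""

from __future__ import annotations

import pandas as pd

from .pipeline import Library
from .srna import CountTable
from .util import dna_to_rna, revcomp

__all__ = ["call_pirna_loci", "chromosome_distribution", "quantify_pirnas"]

_EXCLUDED_CONTEXTS = {"CDS-sense", "CDS-antisense", "tRNA", "rRNA"}


def _eligible(lib: Library) -> pd.DataFrame:
    df = lib.reads
    keep = (
        (df.read_class == "p21U")
        & (df.nhits == 1)
        & ~df.context.isin(_EXCLUDED_CONTEXTS)
        & (df.context != "unmapped")
    )
    return df.loc[keep, ["chrom", "start", "strand", "seq", "count"]]


def call_pirna_loci(
    libraries: list[Library],
    sequences: dict[str, str],
    min_mean_ppm: float = 0.1,
) -> pd.DataFrame:
    """Call 21U-RNA loci from processed libraries.

    Reads of class p21U with a single perfect hit outside CDS/tRNA/rRNA are
    collapsed by (chromosome, start, strand); per-library abundance is
    expressed in ppm of the library's genome-mapped reads, and loci whose
    mean ppm across libraries is >= `min_mean_ppm` are retained (the
    threshold is inclusive). Output is coordinate-sorted with one ppm column
    per library.
    """
    if not libraries:
        raise ValueError("need at least one library")
    genome_ids = {lib.genome_id for lib in libraries}
    if len(genome_ids) > 1:
        raise ValueError(f"libraries mapped against different genomes: {genome_ids}")

    per_lib = []
    for lib in libraries:
        el = _eligible(lib)
        if lib.total_mapped == 0:
            raise ValueError(f"library {lib.name!r} has no mapped reads")
        g = el.groupby(["chrom", "start", "strand"])["count"].sum()
        per_lib.append(g.rename(lib.name))
    mat = pd.concat(per_lib, axis=1).fillna(0.0)
    ppm = mat.copy()
    for lib in libraries:
        ppm[lib.name] = mat[lib.name] / lib.total_mapped * 1e6
    mean_ppm = ppm.mean(axis=1)
    # inclusive threshold, robust to float rounding at the boundary
    keep = mean_ppm >= min_mean_ppm * (1 - 1e-9)
    loci = ppm[keep].reset_index()
    loci["mean_ppm"] = mean_ppm[keep].values
    loci = loci.sort_values(["chrom", "start", "strand"]).reset_index(drop=True)
    loci.insert(0, "locus_id", [f"21ur-{i + 1:05d}" for i in range(len(loci))])
    loci["end"] = loci.start + 21

    seqs = []
    for _, row in loci.iterrows():
        g = sequences[row.chrom][row.start:row.end]
        seqs.append(dna_to_rna(g if row.strand == "+" else revcomp(g)))
    loci["sequence"] = seqs
    cols = (["locus_id", "chrom", "start", "end", "strand", "sequence", "mean_ppm"]
            + [lib.name for lib in libraries])
    return loci[cols]


def chromosome_distribution(loci: pd.DataFrame) -> pd.Series:
    """Fraction of called loci per chromosome (over locus counts, not read
    counts); fractions sum to 1."""
    if len(loci) == 0:
        raise ValueError("no loci")
    return loci.groupby("chrom").size() / len(loci)


def quantify_pirnas(loci: pd.DataFrame, library: Library) -> CountTable:
    """Per-locus raw counts in one library plus miRNA-normalized abundance
    (reads per million miRNA-mapped reads)."""
    if library.total_mirna == 0:
        raise ValueError(f"library {library.name!r} has zero miRNA-mapped reads")
    el = _eligible(library)
    g = el.groupby(["chrom", "start", "strand"])["count"].sum()
    key = pd.MultiIndex.from_frame(loci[["chrom", "start", "strand"]])
    counts = pd.Series(g.reindex(key, fill_value=0).values,
                       index=loci.locus_id, name=library.name)
    table = CountTable(
        counts=counts.to_frame(),
        total_mapped={library.name: library.total_mapped},
        total_mirna={library.name: library.total_mirna},
        total_22g={library.name: library.total_22g},
    )
    return table
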