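"""Flat-file interchange: FASTA, FASTQ, GFF3, BED, bedGraph and TSV.

Internally everything is 0-based half-open; GFF3 (1-based inclusive) is
converted here and nowhere else. bedGraph and BED stay 0-based half-open.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

GFF_COLUMNS = ["seqid", "source", "type", "start", "end",
               "score", "strand", "phase", "attributes"]


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(read_counts: pd.DataFrame, path, prefix: str = "read") -> None:
    """Expand a collapsed (seq, count) table into a plain FASTQ file with
    constant quality (the simulator does not model base quality)."""
    i = 0
    with open(path, "w") as fh:
        for seq, count in zip(read_counts.seq, read_counts["count"]):
            q = "I" * len(seq)
            for _ in range(int(count)):
                fh.write(f"@{prefix}{i}\n{seq}\n+\n{q}\n")
                i += 1


def read_fastq_counts(path) -> pd.DataFrame:
    """Read a FASTQ file into a collapsed (seq, count) table."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for j, line in enumerate(fh):
            if j % 4 == 1:
                s = line.strip().upper()
                counts[s] = counts.get(s, 0) + 1
    return pd.DataFrame({"seq": list(counts), "count": list(counts.values())})


def write_gff3(features: pd.DataFrame, path, source: str = "pirsil") -> None:
    """Write internal features (0-based half-open: chrom/start/end/strand/
    type/id) as GFF3 (1-based inclusive)."""
    df = pd.DataFrame({
        "seqid": features.chrom,
        "source": source,
        "type": features.type,
        "start": features.start + 1,
        "end": features.end,
        "score": ".",
        "strand": features.strand,
        "phase": ".",
        "attributes": "ID=" + features.id.astype(str),
    })
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_gff3(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=GFF_COLUMNS)
    out = pd.DataFrame({
        "id": df.attributes.str.extract(r"ID=([^;]+)")[0],
        "type": df.type,
        "chrom": df.seqid,
        "start": df.start - 1,
        "end": df.end,
        "strand": df.strand,
    })
    return out


def write_bed(intervals: pd.DataFrame, path) -> None:
    """BED6 from columns chrom/start/end/name/score?/strand."""
    df = pd.DataFrame({
        "chrom": intervals.chrom,
        "start": intervals.start,
        "end": intervals.end,
        "name": intervals.get("name", intervals.get("locus_id", ".")),
        "score": intervals.get("score", 0),
        "strand": intervals.get("strand", "."),
    })
    df.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(reference: str, values: np.ndarray, path,
                   decimals: int = 6) -> None:
    """Per-position track as bedGraph (0-based half-open), merging runs of
    equal value."""
    values = np.asarray(values, dtype=float).round(decimals)
    with open(path, "w") as fh:
        if len(values) == 0:
            return
        run_start = 0
        current = values[0]
        for i in range(1, len(values)):
            if values[i] != current:
                fh.write(f"{reference}\t{run_start}\t{i}\t{current:g}\n")
                run_start, current = i, values[i]
        fh.write(f"{reference}\t{run_start}\t{len(values)}\t{current:g}\n")


def read_bedgraph(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end", "value"])


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
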