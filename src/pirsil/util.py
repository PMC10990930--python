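"""Small sequence utilities shared across the package.

Sequences are handled in the DNA alphabet (A, C, G, T) everywhere inside the
pipeline — reads come off the sequencer as cDNA — and converted to RNA
(T → U) only at report boundaries such as duplex prediction and locus tables.
"""

from __future__ import annotations

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")
_RNA_COMP = str.maketrans("ACGUN", "UGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA sequence."""
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_rna(seq: str) -> str:
    """Reverse complement of an RNA sequence."""
    return seq.translate(_RNA_COMP)[::-1]


def dna_to_rna(seq: str) -> str:
    return seq.replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.replace("U", "T")


def check_alphabet(seq: str, alphabet: str = "ACGTN", what: str = "sequence") -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"{what} contains characters outside {alphabet}: {sorted(bad)}")
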