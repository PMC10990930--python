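"""Toy genome construction with planted piRNA loci and target sites.

The genome carries random background sequence, one dominant piRNA cluster on
a designated chromosome (plus a configurable off-cluster fraction scattered
over the other autosomes), a toxin-like target gene (CDS + 3'UTR), a set of
background protein-coding genes that source non-target 22G reads,
annotated miRNA/tRNA/rRNA loci, and a truth table recording everything that
was planted. Identical config + seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..silencing import Transcript
from ..util import revcomp
from .config import SimulationConfig

__all__ = ["GenomeBundle", "PlantedSiteSpec", "build_genome", "plant_target_sites"]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE_PARTNER = {"G": "T", "T": "G"}   # RNA G:U in DNA space
SEED_RANGE = (2, 8)


@dataclass(frozen=True)
class PlantedSiteSpec:
    """Design of one piRNA binding site planted in the target 3'UTR.

    `mismatches_outside_seed` target bases are mutated opposite fixed piRNA
    positions outside the seed; `gu_positions` (1-based piRNA coordinates)
    are converted to G:U wobbles; `bubble` inserts one extra target base
    mid-duplex. With `seed_perfect` set, no deviation may touch piRNA
    positions 2-8.
    """

    pirna_id: str
    target_id: str = "toxin-1"
    utr_offset: int = 0                       # 0-based within the 3'UTR
    mismatches_outside_seed: int = 0
    gu_positions: tuple[int, ...] = ()
    bubble: bool = False
    seed_perfect: bool = True

    def __post_init__(self) -> None:
        # G:U wobbles are valid pairs and may sit in the seed; only true
        # mismatches are banned there (enforced at planting time).
        if len(set(self.gu_positions)) != len(self.gu_positions):
            raise ValueError("duplicate G:U positions")
        if any(p < 1 for p in self.gu_positions):
            raise ValueError("G:U positions are 1-based piRNA coordinates")
        if self.mismatches_outside_seed < 0:
            raise ValueError("mismatch count must be non-negative")


@dataclass
class GenomeBundle:
    config: SimulationConfig
    sequences: dict[str, str]
    features: pd.DataFrame        # id type chrom start end strand (0-based half-open)
    pirna_truth: pd.DataFrame     # locus_id chrom start strand sequence rel_abundance expected_ppm
    target_transcript: Transcript
    planted_sites: list[dict] = field(default_factory=list)
    genome_id: str = "toy"

    @property
    def transcript_sequence(self) -> str:
        t = self.target_transcript
        seq = self.sequences[t.chrom][t.start:t.end]
        return seq if t.strand == "+" else revcomp(seq)


def _random_sequences(config: SimulationConfig, rng: np.random.Generator) -> dict[str, list[str]]:
    return {
        chrom: list(rng.choice(_BASES, size=length))
        for chrom, length in config.chromosomes.items()
    }


def build_genome(config: SimulationConfig | None = None,
                 seed: int | None = None) -> GenomeBundle:
    """Build the toy genome described by `config` (defaults = study
    conditions). `seed` overrides `config.seed`."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    seqs = _random_sequences(config, rng)
    features: list[tuple] = []

    # --- target gene: CDS + 3'UTR on its own chromosome region
    t = config.target
    chrom_len = config.chromosomes[t.chrom]
    gene_len = t.cds_length + t.utr3_length
    gene_start = int(0.375 * chrom_len)
    if gene_start + gene_len > chrom_len:
        raise ValueError("target gene does not fit its chromosome")
    features.append(("toxin-1_cds", "CDS", t.chrom, gene_start,
                     gene_start + t.cds_length, t.strand))
    features.append(("toxin-1_utr3", "three_prime_UTR", t.chrom,
                     gene_start + t.cds_length, gene_start + gene_len, t.strand))
    transcript = Transcript("toxin-1", t.chrom, gene_start,
                            gene_start + gene_len, t.strand)

    # --- background protein-coding genes (22G sources), ncRNA features
    other_chroms = [c for c in config.chromosomes if c != config.cluster.chrom]
    glen = config.background_gene_length
    for i in range(config.n_background_genes):
        chrom = other_chroms[i % len(other_chroms)]
        clen = config.chromosomes[chrom]
        slot = i // len(other_chroms)
        start = int(0.70 * clen) + slot * (glen + 700)
        if start + glen > clen:
            raise ValueError("background genes do not fit; enlarge chromosomes")
        features.append((f"bg-{i + 1:02d}_cds", "CDS", chrom, start,
                         start + glen, "+" if i % 2 == 0 else "-"))

    mirna_chroms = [c for c in other_chroms if c != t.chrom][:2] or other_chroms[:1]
    for i in range(config.n_mirna):
        chrom = mirna_chroms[i % len(mirna_chroms)]
        clen = config.chromosomes[chrom]
        start = int(0.64 * clen) + (i // len(mirna_chroms)) * 150
        features.append((f"mir-{i + 1:02d}", "miRNA", chrom, start, start + 22, "+"))
    trna_chrom = other_chroms[-2] if len(other_chroms) >= 2 else other_chroms[0]
    rrna_chrom = other_chroms[-1]
    for i in range(5):
        clen = config.chromosomes[trna_chrom]
        start = int(0.64 * clen) + i * 300
        features.append((f"trn-{i + 1}", "tRNA", trna_chrom, start, start + 80, "+"))
    for i in range(5):
        clen = config.chromosomes[rrna_chrom]
        start = int(0.64 * clen) + i * 500
        features.append((f"rrn-{i + 1}", "rRNA", rrna_chrom, start, start + 120, "+"))

    # --- piRNA loci: cluster membership per locus, then non-overlapping slots
    cl = config.cluster
    n = cl.n_loci
    on_cluster = rng.random(n) >= cl.off_cluster_fraction
    lo, hi = cl.interval
    step = 60
    cluster_slots = np.arange(lo, hi - 21, step)

    forced: list[int] = []
    if cl.linked_pair_gap is not None and n >= 2:
        # designed tightly linked pair: footprints 21 bp, gap as configured
        p1 = int(lo + 20 * step)
        p2 = p1 + 21 + cl.linked_pair_gap
        if p2 + 21 > hi:
            raise ValueError("linked pair does not fit the cluster interval")
        forced = [p1, p2]
        on_cluster[:2] = True
        cluster_slots = cluster_slots[
            ~((cluster_slots < p1 + 21) & (cluster_slots + 21 > p1))
            & ~((cluster_slots < p2 + 21) & (cluster_slots + 21 > p2))
        ]
    n_free = int(on_cluster.sum()) - len(forced)
    if n_free > len(cluster_slots):
        raise ValueError("cluster interval too small for the requested loci")
    cluster_pos = np.concatenate([
        np.array(forced, dtype=np.int64),
        rng.choice(cluster_slots, size=n_free, replace=False),
    ])
    # off-cluster loci are scattered over the low 2-60% of the other
    # autosomes, away from every gene/ncRNA region placed above
    off_chroms = [c for c in other_chroms if c != t.chrom]
    off_positions: list[tuple[str, int]] = []
    n_off = int(n - on_cluster.sum())
    if n_off:
        chosen = rng.choice(len(off_chroms), size=n_off)
        for ci in chosen:
            chrom = off_chroms[int(ci)]
            clen = config.chromosomes[chrom]
            slots = np.arange(int(0.02 * clen), int(0.60 * clen) - 21, step)
            off_positions.append((chrom, int(rng.choice(slots))))

    strands = rng.choice(np.array(["+", "-"]), size=n)
    rows = []
    ci = oi = 0
    for k in range(n):
        if on_cluster[k]:
            chrom, pos = cl.chrom, int(cluster_pos[ci]); ci += 1
        else:
            chrom, pos = off_positions[oi]; oi += 1
        body = "".join(rng.choice(_BASES, size=20))
        locus_seq = "T" + body                       # 5' T on its strand
        genomic = locus_seq if strands[k] == "+" else revcomp(locus_seq)
        seqs[chrom][pos:pos + 21] = list(genomic)
        rows.append((f"tru21ur-{k + 1:04d}", chrom, pos, strands[k], locus_seq))
    truth = pd.DataFrame(rows, columns=["locus_id", "chrom", "start", "strand", "sequence"])
    truth["end"] = truth.start + 21

    rel = np.exp(rng.normal(0.0, cl.abundance_sigma, size=n))
    rel /= rel.sum()
    truth["rel_abundance"] = rel
    truth["expected_ppm"] = rel * config.library.w_pirna * 1e6
    for _, r in truth.iterrows():
        features.append((r.locus_id, "piRNA", r.chrom, r.start, r.end, r.strand))

    feat = pd.DataFrame(features,
                        columns=["id", "type", "chrom", "start", "end", "strand"])
    bad = feat.merge(pd.Series(config.chromosomes, name="clen"),
                     left_on="chrom", right_index=True)
    if ((bad.start < 0) | (bad.end > bad.clen)).any():
        raise ValueError("a feature falls outside its chromosome")

    sequences = {c: "".join(s) for c, s in seqs.items()}
    return GenomeBundle(
        config=config,
        sequences=sequences,
        features=feat,
        pirna_truth=truth,
        target_transcript=transcript,
    )


def valid_gu_position(pirna: str, preferred: int = 12,
                      seed_range: tuple[int, int] = SEED_RANGE) -> int:
    """Nearest piRNA position to `preferred` (1-based, outside the seed and
    the terminal pairs) whose base can form a G:U wobble (G or T)."""
    lo, hi = seed_range
    m = len(pirna)
    candidates = [p for p in range(2, m)
                  if not lo <= p <= hi and pirna[p - 1] in _WOBBLE_PARTNER]
    if not candidates:
        raise ValueError("piRNA has no wobble-capable position outside the seed")
    return min(candidates, key=lambda p: abs(p - preferred))


def _design_site(pirna: str, spec: PlantedSiteSpec, rng: np.random.Generator) -> tuple[str, dict]:
    """Target-strand (transcript 5'->3') site sequence realizing the spec's
    deviations from the perfect reverse complement of the piRNA."""
    m = len(pirna)
    site = list(revcomp(pirna))          # piRNA position i (1-based) -> site[m - i]
    lo, hi = SEED_RANGE

    for p in spec.gu_positions:
        base = pirna[p - 1]
        if base not in _WOBBLE_PARTNER:
            raise ValueError(
                f"piRNA position {p} has base {base}: cannot form G:U")
        site[m - p] = _WOBBLE_PARTNER[base]

    outside = [p for p in range(1, m + 1)
               if not lo <= p <= hi and p not in spec.gu_positions
               and p not in (1, m)]     # keep terminal pairs intact
    mm_positions = outside[len(outside) // 2:
                           len(outside) // 2 + spec.mismatches_outside_seed]
    if len(mm_positions) < spec.mismatches_outside_seed:
        raise ValueError("not enough positions outside the seed for mismatches")
    for p in mm_positions:
        base = pirna[p - 1]
        choices = [b for b in "ACGT"
                   if b != _COMPLEMENT[base] and b != _WOBBLE_PARTNER.get(base)]
        site[m - p] = choices[int(rng.integers(len(choices)))]
    if spec.seed_perfect and any(lo <= p <= hi for p in mm_positions):
        raise ValueError("mismatch placed inside the seed of a seed-perfect site")

    if spec.bubble:
        # one extra unpaired target base between piRNA positions 10 and 11
        insert_at = m - 10
        site.insert(insert_at, "A")
    design = {
        "mismatch_positions": tuple(mm_positions),
        "gu_positions": tuple(spec.gu_positions),
        "bubble": spec.bubble,
        "site_length": len(site),
    }
    return "".join(site), design


def plant_target_sites(bundle: GenomeBundle, specs: list[PlantedSiteSpec],
                       seed: int = 0) -> GenomeBundle:
    """Edit the target 3'UTR so the reverse complement of each named piRNA
    matches at its designated offset with exactly the designed deviations.
    Overlapping sites are rejected. Mutates and returns the bundle."""
    rng = np.random.default_rng(seed)
    t = bundle.config.target
    utr = bundle.features[bundle.features.id == "toxin-1_utr3"].iloc[0]
    occupied: list[tuple[int, int]] = []
    seq = bundle.sequences[utr.chrom]
    truth_idx = bundle.pirna_truth.set_index("locus_id")

    for spec in specs:
        if spec.pirna_id not in truth_idx.index:
            raise KeyError(f"unknown planted piRNA {spec.pirna_id!r}")
        pirna = truth_idx.loc[spec.pirna_id, "sequence"]
        site, design = _design_site(pirna, spec, rng)
        g_start = int(utr.start) + spec.utr_offset
        g_end = g_start + len(site)
        if g_end > utr.end:
            raise ValueError("planted site does not fit inside the 3'UTR")
        for s, e in occupied:
            if g_start < e and g_end > s:
                raise ValueError("planted sites overlap")
        occupied.append((g_start, g_end))
        # overwrite, keeping chromosome length unchanged
        seq = seq[:g_start] + site + seq[g_start + len(site):]
        bundle.planted_sites.append({
            "pirna_id": spec.pirna_id,
            "target_id": spec.target_id,
            "utr_offset": spec.utr_offset,
            "genome_start": g_start,
            "site_sequence": site,
            **design,
        })
    bundle.sequences[utr.chrom] = seq
    return bundle
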