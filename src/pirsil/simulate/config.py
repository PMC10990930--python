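"""Simulation configuration.

The defaults encode the study conditions the pipeline is meant to recover at
desk scale: a multi-chromosome toy genome whose piRNA loci sit almost
exclusively (96.9%) in one cluster chromosome, a maternal-effect toxin gene
with a 3'UTR open for planted piRNA binding sites, replicate small-RNA
libraries in licensed vs repressed states differing by a 33.7-fold planted
antisense-22G ratio with a 5'-biased positional profile plus
repressed-only 26G reads, ChIP/input pairs with planted enriched intervals,
and Mendelian F2 crosses with genotype- and state-dependent penetrance.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class PiRNAClusterSpec:
    chrom: str = "IV"
    interval: tuple[int, int] = (10_000, 190_000)
    n_loci: int = 1000
    off_cluster_fraction: float = 0.031
    abundance_sigma: float = 1.2      # log-space sd of relative locus abundance
    # when set, the first two loci are placed on the cluster chromosome with
    # exactly this footprint gap (bp) — a designed tightly linked pair that
    # downstream linkage analysis should recover
    linked_pair_gap: int | None = 4600


@dataclass
class TargetGeneSpec:
    chrom: str = "III"
    cds_length: int = 1500
    utr3_length: int = 600
    strand: str = "+"


@dataclass
class LibrarySpec:
    depth: int = 1_000_000
    replicates: int = 4
    # class mixture weights (licensed state, before renormalization); an
    # Argonaute-enriched library is dominated by genuine small-RNA classes.
    # The random-genomic background is kept at the per-position rate a
    # full-size genome would see: the toy genome has ~100x fewer start
    # positions, so the class weight is scaled down accordingly.
    w_pirna: float = 0.44
    w_mirna: float = 0.15
    w_22g: float = 0.40               # all 22G reads (target + other genes)
    w_background: float = 0.01
    target_22g_fraction: float = 0.001  # share of the 22G class antisense to the target (licensed)


@dataclass
class RepressedSpec:
    fold_22g: float = 33.7            # repressed/licensed antisense-22G ratio
    decay_constant: float = 300.0     # nt, exponential 5'-bias decay
    uniform_weight: float = 0.3       # mixture weight of the uniform component
    w_26g: float = 0.002              # repressed-only 26G class weight


@dataclass
class CrossSpec:
    n_f2: int = 200
    # penetrance[state][genotype]
    penetrance: dict = field(default_factory=lambda: {
        "maternal": {"carrier/carrier": 0.0, "carrier/non": 0.0, "non/non": 1.0},
        "paternal": {"carrier/carrier": 0.0, "carrier/non": 0.0, "non/non": 0.094},
    })


@dataclass
class ChipSpec:
    """Enriched intervals are kept a small fraction of the reference: the
    ratio track normalizes each library by its own size, and a large
    enriched share would deflate the ChIP scale factor itself."""

    reference: str = "III"
    reference_length: int = 20_000
    enriched_intervals: tuple = ((9_000, 9_200),)
    enrichment: float = 8.0
    depth: int = 2_000_000            # expected coverage events over the reference


@dataclass
class QpcrSpec:
    fold: float = 0.152               # repressed/licensed target mRNA ratio
    efficiency: float = 1.0
    baseline_ct: float = 26.0
    housekeeping_ct: float = 18.0
    noise_sd: float = 0.2
    replicates: int = 4


@dataclass
class SimulationConfig:
    chromosomes: dict[str, int] = field(default_factory=lambda: {
        "I": 60_000, "II": 60_000, "III": 80_000,
        "IV": 200_000, "V": 60_000, "X": 60_000,
    })
    cluster: PiRNAClusterSpec = field(default_factory=PiRNAClusterSpec)
    target: TargetGeneSpec = field(default_factory=TargetGeneSpec)
    library: LibrarySpec = field(default_factory=LibrarySpec)
    repressed: RepressedSpec = field(default_factory=RepressedSpec)
    cross: CrossSpec = field(default_factory=CrossSpec)
    chip: ChipSpec = field(default_factory=ChipSpec)
    qpcr: QpcrSpec = field(default_factory=QpcrSpec)
    n_background_genes: int = 30
    background_gene_length: int = 1200
    n_mirna: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if any(length <= 0 for length in self.chromosomes.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.cluster.chrom not in self.chromosomes:
            raise ValueError(f"cluster chromosome {self.cluster.chrom!r} missing")
        lo, hi = self.cluster.interval
        if not (0 <= lo < hi <= self.chromosomes[self.cluster.chrom]):
            raise ValueError("cluster interval exceeds chromosome length")
        if not 0 <= self.cluster.off_cluster_fraction <= 1:
            raise ValueError("off-cluster fraction must lie in [0, 1]")
        weights = [self.library.w_pirna, self.library.w_mirna,
                   self.library.w_22g, self.library.w_background,
                   self.repressed.w_26g]
        if any(w < 0 for w in weights):
            raise ValueError("mixture weights must be non-negative")
        if self.repressed.fold_22g < 1:
            raise ValueError("repressed 22G fold must be >= 1")
        for state in self.cross.penetrance.values():
            if any(not 0 <= p <= 1 for p in state.values()):
                raise ValueError("penetrances must lie in [0, 1]")
        if not 0 < self.qpcr.efficiency <= 1:
            raise ValueError("qPCR efficiency must lie in (0, 1]")
        if self.chip.enrichment < 1:
            raise ValueError("ChIP enrichment must be >= 1")
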