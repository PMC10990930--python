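#!/usr/bin/env python
"""Generate one complete synthetic data set at small scale.

Writes the toy genome (FASTA + GFF3), one licensed and one repressed
small-RNA library (FASTQ), simulated F2 cross outcome tables, a ChIP/input
coverage pair (bedGraph) and an RT-qPCR Ct table. Bulky sequence files go
under scratch/sim/; small summary tables under results/.
"""

from pathlib import Path

import pandas as pd

from pirsil import io as pio
from pirsil.simulate import (simulate_chip, simulate_cross, simulate_qpcr,
                             simulate_srna_library, build_genome,
                             plant_target_sites)
from pirsil.workflows import default_site_specs, small_config

SEED = 1
ROOT = Path(__file__).resolve().parent.parent
SCRATCH = pio.ensure_dir(ROOT / "scratch" / "sim")
RESULTS = pio.ensure_dir(ROOT / "results")


def main() -> None:
    config = small_config()
    bundle = build_genome(config, seed=SEED)
    bundle = plant_target_sites(bundle, default_site_specs(bundle), seed=SEED)
    pio.write_fasta(bundle.sequences, SCRATCH / "genome.fa")
    pio.write_gff3(bundle.features, SCRATCH / "features.gff3")
    bundle.pirna_truth.to_csv(SCRATCH / "pirna_truth.tsv", sep="\t", index=False)
    print(f"genome: {sum(map(len, bundle.sequences.values())):,} bp over "
          f"{len(bundle.sequences)} chromosomes; "
          f"{len(bundle.pirna_truth)} planted piRNA loci "
          f"({(bundle.pirna_truth.chrom == config.cluster.chrom).mean():.1%} "
          f"on {config.cluster.chrom}); 2 planted 3'UTR binding sites")

    for state in ("licensed", "repressed"):
        sim = simulate_srna_library(bundle, state, depth=100_000,
                                    seed=SEED + 10, name=state)
        pio.write_fastq(sim.read_counts, SCRATCH / f"srna_{state}.fastq",
                        prefix=state)
        print(f"{state} library: {sim.total:,} reads; truth class counts:",
              sim.truth["class_counts"])

    crosses = pd.concat([simulate_cross(config.cross, st, seed=SEED + i)
                         for i, st in enumerate(("maternal", "paternal"))])
    crosses.to_csv(RESULTS / "simulated_crosses.tsv", sep="\t", index=False)
    nn = crosses[crosses.genotype == "non/non"]
    print("simulated F2 non-carrier delay:",
          {r.state: f"{r.n_delayed}/{r.n}" for r in nn.itertuples()})

    chip, inp = simulate_chip(config.chip, length=config.chip.reference_length,
                              seed=SEED, chip_scale=1.5)
    pio.write_bedgraph(config.chip.reference, chip.values, SCRATCH / "chip.bedgraph")
    pio.write_bedgraph(config.chip.reference, inp.values, SCRATCH / "input.bedgraph")
    print(f"ChIP/input libraries: {chip.library_size:,.0f} / "
          f"{inp.library_size:,.0f} coverage events")

    ct = simulate_qpcr(config.qpcr, seed=SEED)
    ct.to_csv(RESULTS / "qpcr_ct.tsv", sep="\t", index=False)
    print(f"qPCR table written ({len(ct)} reactions, planted fold "
          f"{config.qpcr.fold})")


if __name__ == "__main__":
    main()
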