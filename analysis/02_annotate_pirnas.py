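#!/usr/bin/env python
"""Annotate piRNA (21U-RNA) loci on the full-scale synthetic genome.

Four replicate licensed libraries are simulated, processed (classification,
perfect mapping, context annotation) and collapsed into loci at the
0.1 ppm mean-abundance threshold. The headline check is the chromosomal
distribution: nearly all loci should sit on the planted cluster chromosome
(planted fraction 0.969).
"""

from pathlib import Path

from pirsil import io as pio
from pirsil.workflows import annotate_cluster_fraction

SEED = 1
RESULTS = pio.ensure_dir(Path(__file__).resolve().parent.parent / "results")


def main() -> None:
    res = annotate_cluster_fraction(seed=SEED)
    loci = res["loci"]
    pio.write_bed(loci.rename(columns={"locus_id": "name"}),
                  RESULTS / "pirna_loci.bed")
    res["distribution"].rename("fraction").to_csv(
        RESULTS / "pirna_chromosome_distribution.tsv", sep="\t")
    print(f"called {res['n_called']} piRNA loci "
          f"({res['n_false']} not in the planted truth, "
          f"{res['n_missed']} planted loci missed)")
    print(f"cluster-chromosome fraction: {res['cluster_fraction']:.4f} "
          f"(planted {res['planted_fraction']:.3f})")
    print("per-chromosome distribution:")
    print(res["distribution"].round(4).to_string())


if __name__ == "__main__":
    main()
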