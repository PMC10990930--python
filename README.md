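# pirsil

**piRNA-mediated silencing analysis for nematode small-RNA data.**

In *Caenorhabditis* nematodes, a selfish toxin–antidote element can be shut
down by the host's piRNA (21U-RNA) pathway when it is inherited through the
father: piRNAs recognize the toxin mRNA, trigger amplification of antisense
22G-RNA secondary siRNAs, and establish a transcriptional silencing state
that is inherited for generations. `pirsil` implements the computational
pipeline needed to dissect such an effect:

* **piRNA annotation** — classify small-RNA reads by length and 5′ base
  (21U / 22G / 26G / miRNA), map them perfectly to the genome, and collapse
  uniquely mapping 21U reads outside CDS/tRNA/rRNA context into loci
  retained at a mean abundance ≥ 0.1 ppm;
* **target prediction** — two candidate lists per piRNA set: minimum free
  energy RNA–RNA duplexes under a nearest-neighbor model
  (ΔG = initiation + Σ stacks + Σ loop/bulge penalties + terminal
  penalties), filtered to no bubbles and ≤ 4 mismatches outside the seed
  (piRNA positions 2–8) and ranked by ΔG; and exhaustive ungapped
  alignments (match +1 / mismatch −3) with a perfect seed required, ranked
  by aligned length — plus genetic-linkage pairing of candidate loci;
* **silencing quantification** — antisense 22G/26G coverage and abundance
  over a target transcript (tpm per million class reads),
  licensed-vs-repressed fold changes with an unpaired *t*-test, and
  library-size-normalized ChIP/input ratio tracks;
* **cross statistics** — penetrance, Agresti–Coull 95% binomial intervals
  (p̃ = (k + z²/2)/(n + z²)), two-sided Fisher's exact tests (log-space
  point-probability summation), ΔΔCt fold changes (fold = 2^(−ΔΔCt)) and
  CTCF fluorescence summaries;
* **a synthetic-data generator** — a toy multi-chromosome genome with a
  dominant piRNA cluster (96.9% of loci on one chromosome, including a
  linked binder pair 4.6 kb apart), a toxin gene with plantable 3′UTR
  binding sites, replicate licensed/repressed libraries with a planted
  33.7-fold antisense-22G ratio and 5′-biased coverage, ChIP/input pairs
  with planted enrichment, Mendelian crosses and qPCR tables — so the whole
  pipeline is testable without any sequencing download.

## Worked example

```python
from pirsil.workflows import fold_22g_recovery, cross_statistics

rec = fold_22g_recovery(seed=1)           # 4 vs 4 libraries, 1e6 reads each
f = rec["fold_result"]
print(f"fold {f.fold:.1f}, p = {f.p_value:.2e}")
# fold 32.2, p = 3.38e-13

stats = cross_statistics().set_index("comparison")
print(stats.loc["no_paternal_vs_gen9", ["table", "p_value"]])
# table      [[34,0],[21,6]]
# p_value           0.005331
```

The first block simulates licensed and repressed replicate small-RNA
libraries with a planted 33.7-fold antisense-22G up-regulation of the toxin
transcript, runs them through classification, perfect mapping and
class-normalized quantification, and recovers the planted effect (32.2,
within sampling error) with a decisive two-sided *t*-test. The second
reconstructs a published cross table from its printed percentages (34/34
vs 21/6 delayed worms) and reproduces the printed Fisher p-value 0.0053.

The numbered scripts under `analysis/` run the full story in order:
data simulation, piRNA annotation (96.9% of called loci on the cluster
chromosome), target-candidate ranking (both planted binders rank in the
top 2 of both lists; linkage reports their 4,600 bp separation), silencing
quantification, and the cross statistics. Each writes its tables under
`results/` and prints a short narrative.

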