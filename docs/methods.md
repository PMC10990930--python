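# Methods

## The pipeline and its assumptions

`pirsil` models the computational side of a transgenerational piRNA
silencing study in a selfing nematode. Five analysis layers sit on top of a
synthetic-data generator; every layer is importable on its own.

**Read processing.** Reads live in the DNA alphabet throughout (FASTQ
convention); RNA (T→U) appears only in reports and in duplex prediction.
Classes follow the worm small-RNA nomenclature: 21 nt/5′T (piRNA
candidates), 22 nt/5′G and 26 nt/5′G (secondary/surveillance siRNAs),
miRNA (assigned by mapping context, since miRNA annotation is an input),
everything else "other". Mapping is perfect-only: a read either matches the
genome exactly over its full length or it does not map; the index is a
12-mer-anchored dictionary with full verification, so all occurrences on
both strands are found (reads shorter than the anchor fall back to a naive
scan). Multimapping 21U reads (more than one perfect hit) are excluded from
locus calling — perfect-mapping annotation should not double-count — and
genomic context is resolved with precedence rRNA > tRNA > miRNA > CDS >
intergenic, with CDS split into sense/antisense by relative strand.

**piRNA locus calling.** A locus is a distinct (chromosome, start, strand)
21-bp footprint; identical 21-mers at two positions are two loci (and are
then dropped as multimappers). Per-library abundance is ppm of all
genome-mapped reads of that library; loci are kept when the mean ppm across
libraries is ≥ 0.1, inclusive, with a 1e-9 relative tolerance so a count
that lands exactly on the threshold is not lost to float rounding. The
threshold and the depth are linked: a threshold of 0.1 ppm can only reject
single stray reads if one read is worth less than 0.1 ppm averaged over the
replicates, i.e. depth > 10⁶/(0.1 × replicates) = 2.5 M reads at 4
replicates. The annotation workflow therefore simulates 4 × 4 M reads; the
fold-change workflow, which does not depend on the threshold, uses 4 + 4
libraries of 1 M reads.

**Duplex prediction.** Hybridization only: intermolecular, non-crossing,
antiparallel pairings, no intramolecular structure. The energy of a duplex
with consecutive pairs p₁…p_k is
ΔG = initiation + Σ stack(pᵢ, pᵢ₊₁) + Σ loop penalties + terminal
penalties at both helix ends (counted once for a single-pair duplex).
Parameters are bundled in `src/pirsil/data/stack_params.json`, versioned:
Watson–Crick stacks are the Turner 2004 values; stacks involving G:U
wobbles are approximated as the corresponding A:U-type stack + 0.4 kcal/mol
per wobble (keeping the table symmetric and strictly negative); bulge and
internal-loop penalties are smooth Turner-like size tables capped at a
total loop size of 10. The dynamic program is exact over this model —
states are "last base pair", transitions enumerate loop geometries — and is
vectorized over target positions; backpointers give the pairing structure.
Ties are broken by lowest target start, then lowest piRNA start.
Suboptimal hits come from iterative masking of the winning target interval,
which guarantees non-overlapping footprints and non-decreasing energies.
The test suite holds the DP to *exact* agreement with brute-force
enumeration of all pairing chains; no agreement with any external tool's
ΔG values is claimed.

**Candidate filters.** A mismatch is a 1×1 internal loop; a bubble is any
other loop (bulge or larger/asymmetric internal loop) — the only reading
that keeps "bubble" and "mismatch" distinct. The seed is piRNA positions
2–8 from the 5′ end (the *C. elegans* piRNA-literature convention; the
authors invoke "known targeting rules" without defining them), and is
configurable. The energy list drops hits with bubbles, any seed mismatch
(stated in the source only for outside-seed counts; the stricter reading is
the default and can be relaxed), or more than 4 mismatches outside the
seed, and ranks by ΔG. The continuity list scores every ungapped offset of
the reverse-complemented piRNA (match +1, mismatch −3, exhaustive maximal
segments — a strict superset of word-seeded search), requires the best
segment to cover the seed without mismatches, and ranks by aligned length.
G:U is a valid pair in the energy list (RNA semantics) but a mismatch in
the continuity list (DNA-space alignment semantics). The production scan
uses a per-diagonal match-count bound to skip hopeless offsets; a test
verifies the pruned optimum equals the exhaustive one.

**Silencing quantification.** Antisense coverage over the mature transcript
is scaled per million 22G reads of the library; per-transcript class
abundance is tpm per million class-total reads (the stated per-replicate
22G normalization). With class-total normalization, 26G tpm saturates when
the class is essentially target-only, so 26G values are best read as
presence/absence between states. Fold change is mean(repressed)/
mean(licensed) with a Student (pooled) two-sided unpaired *t*-test by
default; Welch and log2-scale are flags. ChIP/input tracks are each scaled
to counts per million of their own library size, then divided position-wise
with a pseudocount of 0.5 cpm (configurable).

**Cross statistics.** Penetrance is delayed/(delayed + wild type) among
genotyped F2 of the susceptible class. Agresti–Coull uses the exact normal
quantile, never a hard-coded 1.96. The two-sided Fisher p sums
hypergeometric point probabilities ≤ observed × (1 + 1e-7) in log space —
the convention of mainstream implementations, stated here because two-sided
Fisher has competing definitions. Published figures print (percent, n)
pairs; counts are reconstructed by rounding percent × n to the nearest
integer.

## The synthetic-data generator

The generator's defaults are the study conditions at desk scale: a 520-kb,
six-chromosome genome; 1,000 piRNA loci with a 0.031 off-cluster fraction
(so 96.9% sit on chromosome IV), log-normal relative abundances
(σ = 1.2), and the first two loci forced onto the cluster with a 4,600-bp
footprint gap — the designed tightly linked binder pair; a toxin gene
(1.5-kb CDS + 600-bp 3′UTR) on chromosome III plus 30 background coding
genes that source non-target 22G reads; annotated miRNA/tRNA/rRNA loci.
Planted 3′UTR sites realize exactly the designed deviations (outside-seed
mismatches, G:U wobbles at wobble-capable piRNA positions, an optional
1-nt bulge) by overwriting UTR sequence, and the truth table records them.

Libraries allocate their depth by one multinomial draw over read sources —
piRNA loci, miRNAs, background-gene 22Gs, target 22Gs, target 26Gs
(repressed only), random-genomic background — so truth counts sum exactly
to the emitted read count. The repressed state multiplies the target-22G
source weight by 33.7 and switches on the 26G source (weight 0.002).
Default mixture weights (0.44 / 0.15 / 0.40 / 0.01) describe an
Argonaute-enriched (TraPR-style) library; the random-genomic background is
deliberately small because the toy genome has ~100× fewer start positions
than a real one, and a realistic per-position collision rate — which is
what creates recurrent false 21U positions — requires scaling the class
weight down accordingly. Target-22G windows are sampled only where the
antisense copy starts with G (no base is edited, so every read still maps
perfectly), with 5′-window density w·uniform + (1−w)·Exp(λ), w = 0.3,
λ = 300 nt, from the transcript 5′ end; the generative process behind the
real 5′ bias is unknown, and this mixture is a stand-in, not a claim.
Sequencing error is off: perfect-mapping criteria would silently discard
errored reads and break exact truth accounting.

Crosses draw F2 genotypes 1:2:1 and delay as Bernoulli with
genotype×state penetrance (maternal: non-carriers 1.0; paternal:
non-carriers 0.094; carriers 0 — the antidote rescues them). ChIP/input
pairs are Poisson with an 8× planted enrichment over a 200-bp interval of
a 20-kb reference; the interval is kept ≈1% of the reference because cpm
normalization divides by a library total that itself contains the enriched
signal, and combined with the 0.5-cpm pseudocount this bounds the
recoverable ratio a few percent below the planted value (≈7.4 for 8×).
qPCR Ct values shift by −log2(fold)/log2(1 + efficiency) against a
constant housekeeping channel; with efficiency 1 and zero noise the ΔΔCt
estimator recovers the planted fold exactly (planted residuals 15.2% for
mRNA, 20.2% for pre-mRNA).

What the generator does *not* emulate: real nematode genome content and
repeat structure, ligation/PCR bias, base-quality error profiles, piRNA
precursor biology or promoter motifs, and the genome-wide 22G landscape
beyond the planted background genes. Passing tests therefore demonstrate
that the estimators recover planted parameters under the stated sampling
model — not that they would be unbiased on a particular real library.

## Numerical and design choices

* Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
  is converted only at I/O. bedGraph and BED stay 0-based half-open.
* A binder planted as a *perfect* complement gives its piRNA reads a second
  exact genomic match (antisense in the 3′UTR), so that locus is excluded
  from annotation as a multimapper — an inherent consequence of
  perfect-mapping uniqueness, visible in the tests.
* Deterministic tie-breaks everywhere: duplex cell selection by
  (ΔG, target start, piRNA start); Kadane segments keep the first-found
  maximum; candidate ties resolve by score then piRNA id.
* One RNG stream per simulator call; seeds are recorded in library
  metadata, and every workflow derives its sub-seeds from a single seed.
* Degenerate inputs fail loudly: zero normalization denominators name the
  library; empty library sets, mixed genomes, zero-variance t-tests and
  degenerate Fisher margins are all handled explicitly.
* Problem sizes in the standard runs — 4 × 4 M reads for annotation,
  8 × 1 M for fold recovery, ~1,000 piRNAs × 2.1-kb transcript for
  candidate ranking — were chosen as the smallest scales at which the
  planted parameters are identifiable with comfortable margin (threshold
  arithmetic above; binomial noise on the cluster fraction ~0.6%; ~6%
  replicate noise on the fold estimate).

## Known limitations

* The energy parameters are self-consistent, versioned approximations;
  absolute ΔG values are not comparable to any external folding tool, and
  G:U stacking is a single-offset approximation.
* The class-total tpm normalization distorts large fold changes slightly
  (the target's own contribution inflates the denominator in the repressed
  state; ≈3% at the default target share), and the 22G class total also
  contains non-CDS 22-nt/5′G reads (e.g. miRNA-derived), which dilutes
  both states equally.
* Fisher p-values are float sums of log-space terms: identical to full
  enumeration to ~1e-12 in log p, not arbitrary precision.
* `linkage_pairs` is quadratic per chromosome — fine for candidate sets,
  not meant for genome-wide locus lists.
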