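"""Small-RNA library simulation.

Reads are emitted in the DNA alphabet, collapsed to (sequence, count)
tables. One multinomial draw allocates the depth across read sources, so
per-library truth counts sum exactly to the emitted read count:

* 21U — 21-nt reads with 5' T from the planted piRNA loci, multinomial over
  their relative abundances;
* miRNA — annotated miRNA locus sequences, uniform;
* 22G — 22-nt reads with 5' G antisense to coding sequence: a constant pool
  antisense to background genes plus a target-gene pool whose expected size
  scales with the state (repressed = licensed x fold) and whose 5'-window
  position density is a mixture of uniform and exponential decay from the
  transcript 5' end;
* 26G — 26-nt, 5'-G reads antisense to the target, repressed state only;
* background — reads of random length (18-30 nt) from random genomic
  positions and strands.

5'-G classes are realized by sampling windows whose antisense copy starts
with G (no base is ever edited), so every emitted read still maps perfectly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..util import revcomp
from .genome import GenomeBundle

__all__ = ["SimulatedLibrary", "simulate_srna_library"]


@dataclass
class SimulatedLibrary:
    name: str
    state: str                       # "licensed" | "repressed"
    read_counts: pd.DataFrame        # seq, count
    truth: dict
    meta: dict = field(default_factory=dict)

    @property
    def total(self) -> int:
        return int(self.read_counts["count"].sum())


def _antisense_windows(seq: str, length: int) -> tuple[np.ndarray, list[str]]:
    """Valid window starts (transcript coordinates of the window's left
    edge) whose antisense copy begins with G, plus the read sequences."""
    starts = [u for u in range(len(seq) - length + 1)
              if seq[u + length - 1] == "C"]
    reads = [revcomp(seq[u:u + length]) for u in starts]
    return np.array(starts, dtype=np.int64), reads


def simulate_srna_library(
    bundle: GenomeBundle,
    state: str,
    depth: int | None = None,
    seed: int = 0,
    name: str | None = None,
) -> SimulatedLibrary:
    """Simulate one small-RNA library in the licensed or repressed state."""
    if state not in ("licensed", "repressed"):
        raise ValueError("state must be 'licensed' or 'repressed'")
    cfg = bundle.config
    lib = cfg.library
    rep = cfg.repressed
    depth = lib.depth if depth is None else int(depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    if len(bundle.pirna_truth) == 0:
        raise ValueError("bundle has no piRNA loci")
    rng = np.random.default_rng(seed)

    mirna_feats = bundle.features[bundle.features.type == "miRNA"]
    if len(mirna_feats) == 0:
        raise ValueError("bundle has no miRNA loci")
    mirna_seqs = [bundle.sequences[f.chrom][f.start:f.end]
                  for f in mirna_feats.itertuples()]

    tx = bundle.transcript_sequence
    t22_starts, t22_reads = _antisense_windows(tx, 22)
    t26_starts, t26_reads = _antisense_windows(tx, 26)
    if len(t22_starts) == 0:
        raise ValueError("target transcript admits no antisense 22G window")

    bg_reads: list[str] = []
    for f in bundle.features[(bundle.features.type == "CDS")
                             & (bundle.features.id != "toxin-1_cds")].itertuples():
        gseq = bundle.sequences[f.chrom][f.start:f.end]
        if f.strand == "-":
            gseq = revcomp(gseq)
        _, reads = _antisense_windows(gseq, 22)
        bg_reads.extend(reads)

    # source weights; the repressed state scales the target-22G source and
    # switches on the 26G source, then the whole vector is renormalized
    fold = rep.fold_22g if state == "repressed" else 1.0
    w = np.array([
        lib.w_pirna,
        lib.w_mirna,
        lib.w_22g * (1 - lib.target_22g_fraction),
        lib.w_22g * lib.target_22g_fraction * fold,
        rep.w_26g if state == "repressed" else 0.0,
        lib.w_background,
    ])
    n_src = rng.multinomial(depth, w / w.sum())
    n_pirna, n_mirna, n_bg22, n_t22, n_t26, n_noise = (int(x) for x in n_src)

    parts: list[pd.DataFrame] = []
    truth: dict = {
        "class_counts": {
            "pirna_21u": n_pirna, "mirna": n_mirna, "background_22g": n_bg22,
            "target_22g": n_t22, "target_26g": n_t26, "background": n_noise,
        },
        "state": state,
    }

    loc_counts = rng.multinomial(n_pirna, bundle.pirna_truth.rel_abundance.values)
    truth["locus_counts"] = pd.Series(loc_counts,
                                      index=bundle.pirna_truth.locus_id.values)
    nz = loc_counts > 0
    parts.append(pd.DataFrame({
        "seq": bundle.pirna_truth.sequence.values[nz],
        "count": loc_counts[nz],
    }))

    mir_counts = rng.multinomial(n_mirna, np.full(len(mirna_seqs), 1 / len(mirna_seqs)))
    parts.append(pd.DataFrame({"seq": mirna_seqs, "count": mir_counts}))

    # target 22G: 5'-biased mixture density over valid window starts
    u = t22_starts.astype(float)
    dens = (rep.uniform_weight / len(u)
            + (1 - rep.uniform_weight)
            * np.exp(-u / rep.decay_constant)
            / np.exp(-u / rep.decay_constant).sum())
    dens /= dens.sum()
    t22_counts = rng.multinomial(n_t22, dens)
    truth["target22_positions"] = pd.Series(t22_counts, index=t22_starts)
    parts.append(pd.DataFrame({"seq": t22_reads, "count": t22_counts}))

    if n_t26:
        dens26 = np.full(len(t26_starts), 1 / len(t26_starts))
        t26_counts = rng.multinomial(n_t26, dens26)
        parts.append(pd.DataFrame({"seq": t26_reads, "count": t26_counts}))
        truth["target26_positions"] = pd.Series(t26_counts, index=t26_starts)

    bg_counts = rng.multinomial(n_bg22, np.full(len(bg_reads), 1 / len(bg_reads)))
    parts.append(pd.DataFrame({"seq": bg_reads, "count": bg_counts}))

    if n_noise:
        chroms = list(bundle.sequences)
        lens = np.array([len(bundle.sequences[c]) for c in chroms], dtype=float)
        ci = rng.choice(len(chroms), size=n_noise, p=lens / lens.sum())
        rl = rng.integers(18, 31, size=n_noise)
        minus = rng.random(n_noise) < 0.5
        seqs = []
        for k in range(n_noise):
            c = chroms[int(ci[k])]
            L = int(rl[k])
            pos = int(rng.integers(0, len(bundle.sequences[c]) - L))
            s = bundle.sequences[c][pos:pos + L]
            seqs.append(revcomp(s) if minus[k] else s)
        parts.append(pd.DataFrame({"seq": seqs, "count": np.ones(n_noise, dtype=np.int64)}))

    reads = (pd.concat(parts, ignore_index=True)
             .groupby("seq", as_index=False)["count"].sum()
             .sort_values("seq", ignore_index=True))
    reads = reads[reads["count"] > 0].reset_index(drop=True)
    return SimulatedLibrary(
        name=name or f"{state}-{seed}",
        state=state,
        read_counts=reads,
        truth=truth,
        meta={"seed": seed, "depth": depth, "state": state,
              "fold_22g": fold, "weights": w.tolist()},
    )
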