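"""piRNA -> target candidate prediction and ranking.

Two complementary candidate procedures are implemented:

* an energy list — for each piRNA the best hybridization duplexes against the
  target mRNA are predicted (``pirsil.duplex``), hits with bubbles (any loop
  other than a 1x1 mismatch) or with mismatches in the seed, or with more
  than a configurable number of mismatches outside the seed, are discarded,
  and the survivors are ranked by free energy (most negative first);

* a continuity list — every ungapped offset of the reverse-complemented
  piRNA against the target is scored (match +1 / mismatch -3, exhaustive
  maximal-segment search, no heuristic seeding), piRNAs whose best alignment
  covers the seed region without mismatches are kept, and candidates are
  ranked by the total length of the ungapped alignment.

The seed region defaults to piRNA positions 2-8 (1-based from the 5' end),
the convention of the Caenorhabditis piRNA-targeting literature. G:U wobbles
count as valid pairs in the energy list (RNA duplex semantics) but as
mismatches in the continuity list (DNA-space alignment semantics).

``linkage_pairs`` reports pairs of candidate piRNA loci in tight genetic
linkage (same chromosome within a distance cutoff), which is how co-acting
piRNA pairs are spotted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .duplex import DuplexHit, EnergyParams, suboptimal_duplexes
from .util import dna_to_rna, revcomp, rna_to_dna

__all__ = [
    "UngappedAlignment",
    "CandidateRecord",
    "ungapped_local_alignments",
    "best_ungapped_alignment",
    "filter_and_rank_energy",
    "filter_and_rank_continuity",
    "energy_candidates",
    "continuity_candidates",
    "linkage_pairs",
]

SEED_DEFAULT = (2, 8)


@dataclass(frozen=True)
class UngappedAlignment:
    pirna_id: str
    target_id: str
    pirna_start: int       # 0-based on the piRNA (5'->3')
    target_start: int      # 0-based on the target
    length: int
    matches: int
    mismatch_positions: tuple[int, ...]  # piRNA coordinates, 1-based from 5'
    score: int


@dataclass(frozen=True)
class CandidateRecord:
    pirna_id: str
    method: str            # "energy" | "continuity"
    rank: int
    key: float             # dG (energy) or aligned length (continuity)
    best_hit: object       # DuplexHit or UngappedAlignment


def _offset_segments(cmp_vec: np.ndarray, match: int, mismatch: int):
    """Best positive-scoring contiguous segment of a match/mismatch vector
    (Kadane); deterministic: first-encountered maximum wins. Returns
    (start, end, score, matches) or None."""
    scores = np.where(cmp_vec, match, mismatch)
    best = None
    run_start, run_score = 0, 0
    for k, s in enumerate(scores):
        if run_score <= 0:
            run_start, run_score = k, int(s)
        else:
            run_score += int(s)
        if run_score > 0 and (best is None or run_score > best[2]):
            best = (run_start, k + 1, run_score, 0)
    if best is None:
        return None
    a, b, sc, _ = best
    return a, b, sc, int(cmp_vec[a:b].sum())


def ungapped_local_alignments(
    pirna: str,
    target: str,
    match: int = 1,
    mismatch: int = -3,
    *,
    pirna_id: str = "",
    target_id: str = "",
) -> list[UngappedAlignment]:
    """All positive-scoring maximal ungapped segments of the
    reverse-complemented piRNA against the target (DNA alphabet), one per
    offset. Exhaustive: every offset, including partial overlaps, is scored,
    so the output is a superset of what word-seeded search would find."""
    p = rna_to_dna(pirna)
    t = rna_to_dna(target)
    q = revcomp(p)
    m, n = len(q), len(t)
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    ta = np.frombuffer(t.encode(), dtype=np.uint8)
    out: list[UngappedAlignment] = []
    for off in range(-(m - 1), n):
        q_lo = max(0, -off)
        q_hi = min(m, n - off)
        if q_hi - q_lo <= 0:
            continue
        cmp_vec = qa[q_lo:q_hi] == ta[off + q_lo:off + q_hi]
        seg = _offset_segments(cmp_vec, match, mismatch)
        if seg is None:
            continue
        a, b, score, matches = seg
        qs, qe = q_lo + a, q_lo + b      # on the reverse complement
        mism = tuple(
            sorted(m - (qs + k) for k in range(qe - qs) if not cmp_vec[a + k])
        )
        out.append(
            UngappedAlignment(
                pirna_id=pirna_id,
                target_id=target_id,
                pirna_start=m - qe,      # revcomp index -> piRNA index
                target_start=off + qs,
                length=qe - qs,
                matches=matches,
                mismatch_positions=mism,
                score=score,
            )
        )
    return out


def best_ungapped_alignment(
    pirna: str,
    target: str,
    match: int = 1,
    mismatch: int = -3,
    **ids,
) -> UngappedAlignment | None:
    """Best ungapped alignment by (length, score); None when no offset
    yields a positive score. Offsets are pruned with a per-diagonal match
    count bound, which cannot change the optimum: a segment of length L with
    positive score needs more than 3L/4 matches on its diagonal."""
    p = rna_to_dna(pirna)
    t = rna_to_dna(target)
    q = revcomp(p)
    m, n = len(q), len(t)
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    ta = np.frombuffer(t.encode(), dtype=np.uint8)
    # match positions -> diagonal histogram
    eq = qa[:, None] == ta[None, :]
    qi, tj = np.nonzero(eq)
    diags = tj - qi + (m - 1)          # diagonal id = off + m - 1
    counts = np.bincount(diags, minlength=n + m - 1)
    order = np.argsort(counts)[::-1]
    best: UngappedAlignment | None = None
    for d in order:
        c = int(counts[d])
        if c == 0:
            break
        # max achievable length on this diagonal: matches + mismatches with
        # score > 0  =>  length < c + c/3 + 1
        bound = c + (c - 1) // 3 + 1
        if best is not None and (bound < best.length or
                                 (bound == best.length and c < best.score)):
            if bound < best.length:
                break
            continue
        off = int(d) - (m - 1)
        q_lo = max(0, -off)
        q_hi = min(m, n - off)
        cmp_vec = qa[q_lo:q_hi] == ta[off + q_lo:off + q_hi]
        seg = _offset_segments(cmp_vec, match, mismatch)
        if seg is None:
            continue
        a, b, score, matches = seg
        qs, qe = q_lo + a, q_lo + b
        cand = UngappedAlignment(
            pirna_id=ids.get("pirna_id", ""),
            target_id=ids.get("target_id", ""),
            pirna_start=m - qe,
            target_start=off + qs,
            length=qe - qs,
            matches=matches,
            mismatch_positions=tuple(
                sorted(m - (qs + k) for k in range(qe - qs) if not cmp_vec[a + k])
            ),
            score=score,
        )
        if best is None or (cand.length, cand.score) > (best.length, best.score):
            best = cand
    return best


def filter_and_rank_energy(
    hits_per_pirna: dict[str, list[DuplexHit]],
    max_outside_seed_mismatch: int = 4,
    *,
    allow_inside_seed: bool = False,
) -> list[CandidateRecord]:
    """Keep hits without bubbles, without seed mismatches (configurable) and
    with at most `max_outside_seed_mismatch` mismatches outside the seed;
    each piRNA is represented by its best surviving hit and candidates are
    ranked by free energy, most negative first."""
    best: list[tuple[float, str, DuplexHit]] = []
    for pid, hits in hits_per_pirna.items():
        ok = [
            h for h in hits
            if not h.bubble
            and (allow_inside_seed or h.mismatches_inside_seed == 0)
            and h.mismatches_outside_seed <= max_outside_seed_mismatch
        ]
        if ok:
            top = min(ok, key=lambda h: (h.energy, h.target_interval[0]))
            best.append((top.energy, pid, top))
    best.sort(key=lambda x: (x[0], x[1]))
    return [
        CandidateRecord(pirna_id=pid, method="energy", rank=r + 1, key=e, best_hit=h)
        for r, (e, pid, h) in enumerate(best)
    ]


def filter_and_rank_continuity(
    alignments_per_pirna: dict[str, list[UngappedAlignment]],
    seed: tuple[int, int] = SEED_DEFAULT,
) -> list[CandidateRecord]:
    """Keep piRNAs whose best alignment covers the full seed region with no
    mismatches there; rank by aligned length (descending), ties broken by
    score then piRNA id."""
    lo, hi = seed
    kept: list[tuple[int, int, str, UngappedAlignment]] = []
    for pid, alns in alignments_per_pirna.items():
        if not alns:
            continue
        top = max(alns, key=lambda a: (a.length, a.score))
        # seed positions (1-based from the piRNA 5') covered by the segment
        cov_lo = top.pirna_start + 1
        cov_hi = top.pirna_start + top.length
        covers_seed = cov_lo <= lo and cov_hi >= hi
        clean_seed = not any(lo <= p <= hi for p in top.mismatch_positions)
        if covers_seed and clean_seed:
            kept.append((-top.length, -top.score, pid, top))
    kept.sort()
    return [
        CandidateRecord(pirna_id=pid, method="continuity", rank=r + 1,
                        key=float(-negl), best_hit=a)
        for r, (negl, _negs, pid, a) in enumerate(kept)
    ]


def energy_candidates(
    pirnas: dict[str, str],
    target: str,
    params: EnergyParams | None = None,
    k: int = 5,
    max_outside_seed_mismatch: int = 4,
    seed: tuple[int, int] = SEED_DEFAULT,
    target_id: str = "target",
) -> list[CandidateRecord]:
    """End-to-end energy list: suboptimal duplexes per piRNA, then filter and
    rank. Sequences may be DNA or RNA; hybridization runs in RNA space."""
    t_rna = dna_to_rna(target)
    hits = {
        pid: suboptimal_duplexes(dna_to_rna(seq), t_rna, params, k,
                                 seed=seed, pirna_id=pid, target_id=target_id)
        for pid, seq in pirnas.items()
    }
    return filter_and_rank_energy(hits, max_outside_seed_mismatch)


def continuity_candidates(
    pirnas: dict[str, str],
    target: str,
    match: int = 1,
    mismatch: int = -3,
    seed: tuple[int, int] = SEED_DEFAULT,
    target_id: str = "target",
) -> list[CandidateRecord]:
    """End-to-end continuity list using the pruned best-alignment search."""
    alns = {}
    for pid, seq in pirnas.items():
        best = best_ungapped_alignment(seq, target, match, mismatch,
                                       pirna_id=pid, target_id=target_id)
        alns[pid] = [best] if best is not None else []
    return filter_and_rank_continuity(alns, seed)


def linkage_pairs(loci: pd.DataFrame, max_distance: int) -> pd.DataFrame:
    """All same-chromosome pairs of candidate piRNA loci whose footprints are
    separated by at most `max_distance` bp. Distance is the gap between
    footprints (0 for adjacent or overlapping loci).

    `loci` needs columns: locus_id, chrom, start, end.
    """
    rows = []
    for _, sub in loci.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "locus_id"]).reset_index(drop=True)
        for i in range(len(sub)):
            for j in range(i + 1, len(sub)):
                gap = max(0, int(sub.start[j]) - int(sub.end[i]))
                if gap <= max_distance:
                    rows.append(
                        (sub.locus_id[i], sub.locus_id[j], sub.chrom[i], gap)
                    )
    return pd.DataFrame(rows, columns=["locus_a", "locus_b", "chrom", "distance"])
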