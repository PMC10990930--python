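"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different route from the code under test:
exhaustive enumeration for duplex energies and Fisher p-values, direct
textbook formulas for the t statistic, and naive string scanning for
perfect mapping.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from pirsil.duplex import PAIR_CODE, EnergyParams

_COMP = str.maketrans("ACGTN", "TGCAN")


def chain_energy(pirna: str, target: str, chain, params: EnergyParams) -> float:
    """Energy of one explicit monotone pairing chain."""
    codes = [PAIR_CODE[(pirna[i], target[j])] for i, j in chain]
    e = params.initiation
    if len(chain) == 1:
        return e + float(params.terminal_penalty[codes[0]])
    e += float(params.terminal_penalty[codes[0]]) + float(params.terminal_penalty[codes[-1]])
    for (i1, j1), (i2, j2), c1, c2 in zip(chain, chain[1:], codes, codes[1:]):
        a, b = i2 - i1 - 1, j1 - j2 - 1
        e += float(params.stack[c1, c2]) if (a == 0 and b == 0) else params.loop_cost(a, b)
    return e


def brute_force_duplex_mfe(pirna: str, target: str, params: EnergyParams):
    """Minimum duplex energy by explicit enumeration of every monotone
    pairing chain (loop sizes capped as in the model)."""
    cells = [(i, j) for i in range(len(pirna)) for j in range(len(target))
             if (pirna[i], target[j]) in PAIR_CODE]
    best = np.inf
    stack = [[c] for c in cells]
    while stack:
        chain = stack.pop()
        best = min(best, chain_energy(pirna, target, chain, params))
        i0, j0 = chain[-1]
        for (i, j) in cells:
            a, b = i - i0 - 1, j0 - j - 1
            if a >= 0 and b >= 0 and a + b <= params.max_loop:
                stack.append(chain + [(i, j)])
    return None if not np.isfinite(best) else float(best)


def fisher_two_sided_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    lo, hi = max(0, col1 - row2), min(col1, row1)
    pmf = {x: sps.hypergeom.pmf(x, n, row1, col1) for x in range(lo, hi + 1)}
    obs = pmf[a]
    return float(min(1.0, sum(p for p in pmf.values() if p <= obs * (1 + 1e-7))))


def student_t_textbook(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample t statistic and two-sided p from the
    textbook formulas."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2 * sps.t.sf(abs(t), nx + ny - 2)
    return float(t), float(p)


def naive_map(seq: str, sequences: dict[str, str]):
    """All perfect full-length occurrences by naive scanning, both strands;
    returns sorted (chrom, start, strand) triples."""
    if "N" in seq:
        return []
    rc = seq.translate(_COMP)[::-1]
    hits = []
    for chrom, ref in sequences.items():
        for probe, strand in ((seq, "+"), (rc, "-")):
            start = ref.find(probe)
            while start != -1:
                hits.append((chrom, start, strand))
                start = ref.find(probe, start + 1)
    return sorted(hits)


def best_segment_bruteforce(qseq: str, tseq: str, match: int = 1,
                            mismatch: int = -3):
    """Best ungapped segment over every offset and every sub-segment, by
    exhaustive search. Returns (length, score) of the optimum or None."""
    best = None
    m, n = len(qseq), len(tseq)
    for off in range(-(m - 1), n):
        q_lo, q_hi = max(0, -off), min(m, n - off)
        for s in range(q_lo, q_hi):
            for e in range(s + 1, q_hi + 1):
                sc = sum(match if qseq[k] == tseq[off + k] else mismatch
                         for k in range(s, e))
                if sc > 0:
                    cand = (e - s, sc)
                    if best is None or (sc, e - s) > (best[1], best[0]):
                        best = cand
    return best
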