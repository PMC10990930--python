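"""Intermolecular RNA–RNA duplex minimum-free-energy prediction.

A piRNA recognizes its target by hybridizing with the mRNA, and the stability
of the hybrid — approximated with a nearest-neighbor free-energy model — is
used to rank candidate target sites. This module computes the
minimum-free-energy duplex between two RNA strands under a bundled,
versioned nearest-neighbor parameter table: stacking energies for all ordered
pairs of adjacent base pairs over {A:U, U:A, C:G, G:C, G:U, U:G}, a duplex
initiation penalty, terminal A:U / G:U penalties, and size-dependent bulge
and internal-loop penalties capped at a maximum loop size.

The model considers only intermolecular, non-crossing, antiparallel pairings
(no intramolecular structure), matching the hybridization-only setting. The
energy of a duplex whose consecutive base pairs are (i1,j1), ..., (ik,jk)
(piRNA index ascending, target index descending) is

    dG = initiation + sum of stack/loop terms between consecutive pairs
         + terminal penalties at both helix ends

with the terminal penalty counted once for a single-pair duplex.

Dynamic programming over "last base pair" states gives the exact optimum;
the recursion is vectorized over target positions so scanning a full piRNA
complement against a multi-kilobase transcript stays fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .util import check_alphabet

__all__ = [
    "EnergyParams",
    "DuplexHit",
    "load_default_params",
    "duplex_minimum_energy",
    "suboptimal_duplexes",
]

# Pair codes: (strand1 base, strand2 base) -> code. Strand1 is the piRNA
# read 5'->3'; strand2 the target, running antiparallel.
PAIR_STR = ["AU", "UA", "CG", "GC", "GU", "UG"]
PAIR_CODE = {("A", "U"): 0, ("U", "A"): 1, ("C", "G"): 2,
             ("G", "C"): 3, ("G", "U"): 4, ("U", "G"): 5}
_BASE_ORD = {"A": 0, "C": 1, "G": 2, "U": 3}
_PAIR_CODE_MAT = -np.ones((4, 4), dtype=np.int8)
for (b1, b2), c in PAIR_CODE.items():
    _PAIR_CODE_MAT[_BASE_ORD[b1], _BASE_ORD[b2]] = c
_WOBBLE_CODES = (4, 5)


@dataclass(frozen=True)
class EnergyParams:
    """Nearest-neighbor duplex parameters (kcal/mol)."""

    stack: np.ndarray          # (6, 6) array indexed by [prev pair, next pair]
    initiation: float
    terminal_penalty: np.ndarray  # (6,) per closing-pair code
    bulge: np.ndarray          # penalty by bulge size, index 1..max_loop
    internal: np.ndarray       # penalty by total internal-loop size, 2..max_loop
    max_loop: int
    version: str = "unversioned"

    def __post_init__(self) -> None:
        if self.stack.shape != (6, 6):
            raise ValueError("stack table must cover all 36 ordered stacks")
        if not (self.stack < 0).all():
            raise ValueError("stack free energies must be negative")
        if self.initiation < 0 or (self.terminal_penalty < 0).any():
            raise ValueError("initiation and terminal penalties must be >= 0")

    def loop_cost(self, a: int, b: int) -> float:
        """Penalty for a loop with `a` unpaired piRNA bases and `b` unpaired
        target bases between consecutive pairs ((0,0) is a stack and has no
        loop cost here)."""
        s = a + b
        if s == 0:
            return 0.0
        if s > self.max_loop:
            return float("inf")
        if a == 0 or b == 0:
            return float(self.bulge[s])
        return float(self.internal[s])


def load_default_params() -> EnergyParams:
    """Load the bundled, versioned parameter table."""
    raw = json.loads(
        resources.files("pirsil.data").joinpath("stack_params.json").read_text()
    )
    stack = np.zeros((6, 6))
    for i, p1 in enumerate(PAIR_STR):
        for j, p2 in enumerate(PAIR_STR):
            key = p1[0] + p2[0] + "/" + p1[1] + p2[1]
            stack[i, j] = raw["stack"][key]
    max_loop = int(raw["max_loop"])
    bulge = np.full(max_loop + 1, np.inf)
    for k, v in raw["bulge"].items():
        if int(k) <= max_loop:
            bulge[int(k)] = v
    internal = np.full(max_loop + 1, np.inf)
    for k, v in raw["internal"].items():
        if int(k) <= max_loop:
            internal[int(k)] = v
    term = np.array([raw["terminal_au_gu_penalty"] if PAIR_STR[c] in
                     ("AU", "UA", "GU", "UG") else 0.0 for c in range(6)])
    return EnergyParams(
        stack=stack,
        initiation=float(raw["duplex_initiation"]),
        terminal_penalty=term,
        bulge=bulge,
        internal=internal,
        max_loop=max_loop,
        version=str(raw["version"]),
    )


@dataclass
class DuplexHit:
    """One predicted piRNA:target hybrid."""

    pirna_id: str
    target_id: str
    pairs: list[tuple[int, int]]            # (piRNA index, target index), 0-based
    energy: float                           # dG, kcal/mol
    pirna_interval: tuple[int, int]         # 0-based half-open on the piRNA
    target_interval: tuple[int, int]        # 0-based half-open on the target
    pairing_string: str                     # "<piRNA structure>&<target structure>"
    mismatches_outside_seed: int
    mismatches_inside_seed: int
    mismatch_positions: list[int] = field(default_factory=list)  # piRNA, 1-based
    gu_count: int = 0
    bubble: bool = False
    seed_perfect: bool = False


def _encode(seq: str, what: str) -> np.ndarray:
    check_alphabet(seq, "ACGU", what)
    return np.fromiter((_BASE_ORD[c] for c in seq), dtype=np.int8, count=len(seq))


def _pair_codes(pirna: np.ndarray, target: np.ndarray) -> np.ndarray:
    return _PAIR_CODE_MAT[pirna[:, None], target[None, :]]


def _dp(codes: np.ndarray, params: EnergyParams):
    """Fill the DP tables. f[i, j] = best energy of a partial duplex whose
    last pair (largest piRNA index, smallest target index) is (i, j),
    including initiation and the terminal penalty of the first pair.
    bp[i, j] encodes the loop geometry back to the previous pair
    (a * (max_loop + 1) + b), or -2 when (i, j) opens the duplex."""
    m, n = codes.shape
    L = params.max_loop
    pairable = codes >= 0
    term = np.where(pairable, params.terminal_penalty[np.clip(codes, 0, 5)], np.inf)
    f = np.full((m, n), np.inf)
    bp = np.full((m, n), -1, dtype=np.int32)
    f[pairable] = params.initiation + term[pairable]
    bp[pairable] = -2

    geometries = [(a, b) for a in range(L + 1) for b in range(L + 1 - a)]
    for i in range(1, m):
        row_codes = codes[i]
        row_ok = pairable[i]
        for a, b in geometries:
            ip = i - 1 - a
            if ip < 0:
                continue
            # previous pair at (ip, j + 1 + b) for current j in [0, n - 2 - b]
            width = n - 1 - b
            if width <= 0:
                continue
            prev = f[ip, 1 + b:]
            if a == 0 and b == 0:
                pc = codes[ip, 1:]
                cc = row_codes[:width]
                with np.errstate(invalid="ignore"):
                    cost = np.where(
                        (pc >= 0) & (cc >= 0),
                        params.stack[np.clip(pc, 0, 5), np.clip(cc, 0, 5)],
                        np.inf,
                    )
                cand = prev + cost
            else:
                cand = prev + params.loop_cost(a, b)
            better = row_ok[:width] & (cand < f[i, :width])
            if better.any():
                f[i, :width][better] = cand[better]
                bp[i, :width][better] = a * (L + 1) + b
    return f, bp, term


def _traceback(bp: np.ndarray, i: int, j: int, max_loop: int) -> list[tuple[int, int]]:
    pairs = [(i, j)]
    while bp[i, j] != -2:
        code = bp[i, j]
        a, b = divmod(int(code), max_loop + 1)
        i = i - 1 - a
        j = j + 1 + b
        pairs.append((i, j))
    pairs.reverse()
    return pairs


def _annotate(
    pirna: str,
    target: str,
    pairs: list[tuple[int, int]],
    energy: float,
    seed: tuple[int, int],
    pirna_id: str,
    target_id: str,
) -> DuplexHit:
    """Classify loop geometry between consecutive pairs into mismatches
    (1x1 internal loops) and bubbles (anything larger or asymmetric), count
    G:U wobbles, and check seed pairing. Seed bounds are 1-based inclusive
    piRNA positions."""
    codes = [PAIR_CODE[(pirna[i], target[j])] for i, j in pairs]
    gu = sum(1 for c in codes if c in _WOBBLE_CODES)
    mismatch_pos: list[int] = []
    bubble = False
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        a = i2 - i1 - 1
        b = j1 - j2 - 1
        if a == 0 and b == 0:
            continue
        if a == 1 and b == 1:
            mismatch_pos.append(i1 + 2)  # 1-based piRNA position of the loop
        else:
            bubble = True
    lo, hi = seed
    inside = sum(1 for p in mismatch_pos if lo <= p <= hi)
    outside = len(mismatch_pos) - inside
    paired_pirna = {i for i, _ in pairs}
    seed_perfect = all(p - 1 in paired_pirna for p in range(lo, hi + 1)) and inside == 0

    i_lo, i_hi = pairs[0][0], pairs[-1][0]
    j_lo, j_hi = pairs[-1][1], pairs[0][1]
    prow = ["." for _ in range(i_lo, i_hi + 1)]
    trow = ["." for _ in range(j_lo, j_hi + 1)]
    for i, j in pairs:
        prow[i - i_lo] = "("
        trow[j - j_lo] = ")"
    return DuplexHit(
        pirna_id=pirna_id,
        target_id=target_id,
        pairs=pairs,
        energy=round(float(energy), 6),
        pirna_interval=(i_lo, i_hi + 1),
        target_interval=(j_lo, j_hi + 1),
        pairing_string="".join(prow) + "&" + "".join(trow),
        mismatches_outside_seed=outside,
        mismatches_inside_seed=inside,
        mismatch_positions=mismatch_pos,
        gu_count=gu,
        bubble=bubble,
        seed_perfect=seed_perfect,
    )


def duplex_minimum_energy(
    pirna: str,
    target: str,
    params: EnergyParams | None = None,
    *,
    seed: tuple[int, int] = (2, 8),
    pirna_id: str = "",
    target_id: str = "",
    _mask: np.ndarray | None = None,
) -> DuplexHit | None:
    """Minimum-free-energy intermolecular duplex between an RNA piRNA and an
    RNA target, or None when no base pair can form.

    Ties are broken deterministically: lowest target start, then lowest
    piRNA start. `_mask` marks target positions excluded from pairing (used
    for suboptimal enumeration).
    """
    if params is None:
        params = load_default_params()
    if not pirna or not target:
        raise ValueError("sequences must be non-empty")
    p = _encode(pirna, "piRNA")
    t = _encode(target, "target")
    codes = _pair_codes(p, t)
    if _mask is not None:
        codes = codes.copy()
        codes[:, _mask] = -1
    if (codes < 0).all():
        return None
    f, bp, term = _dp(codes, params)
    # terminal penalty at the closing (last-pair) end; single-pair duplexes
    # carry the penalty once, at initiation.
    total = f + np.where(bp == -2, 0.0, term)
    best = np.nanmin(total[np.isfinite(total)]) if np.isfinite(total).any() else np.inf
    if not np.isfinite(best):
        return None
    ii, jj = np.nonzero(np.isclose(total, best, rtol=0, atol=1e-9))
    candidates = []
    for i, j in zip(ii.tolist(), jj.tolist()):
        pairs = _traceback(bp, i, j, params.max_loop)
        candidates.append((pairs[-1][1], pairs[0][0], pairs))
    candidates.sort(key=lambda c: (c[0], c[1]))
    pairs = candidates[0][2]
    return _annotate(pirna, target, pairs, best, seed, pirna_id, target_id)


def suboptimal_duplexes(
    pirna: str,
    target: str,
    params: EnergyParams | None = None,
    k: int = 5,
    *,
    seed: tuple[int, int] = (2, 8),
    pirna_id: str = "",
    target_id: str = "",
) -> list[DuplexHit]:
    """Up to k duplexes with distinct, non-overlapping target intervals,
    found by iteratively masking the target footprint of each best hit.
    Energies are non-decreasing because each search space nests in the last.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if params is None:
        params = load_default_params()
    mask = np.zeros(len(target), dtype=bool)
    hits: list[DuplexHit] = []
    for _ in range(k):
        hit = duplex_minimum_energy(
            pirna, target, params, seed=seed,
            pirna_id=pirna_id, target_id=target_id, _mask=mask,
        )
        if hit is None:
            break
        hits.append(hit)
        mask[hit.target_interval[0]:hit.target_interval[1]] = True
    return hits
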