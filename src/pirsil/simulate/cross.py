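"""Mendelian F2 cross simulation with genotype- and state-dependent
penetrance.

F2 individuals from a heterozygous F1 self-cross segregate 1:2:1 into
carrier/carrier : carrier/non-carrier : non-carrier/non-carrier. Whether a
worm is scored as developmentally delayed is a Bernoulli draw with a
penetrance that depends on its genotype and on the inheritance state of the
toxin-antidote element (maternal vs paternal), emulating maternal toxin
poisoning countered by the zygotic antidote in carriers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..stats import CrossGroup
from .config import CrossSpec

__all__ = ["simulate_cross", "GENOTYPES"]

GENOTYPES = ["carrier/carrier", "carrier/non", "non/non"]
_MENDEL = np.array([0.25, 0.5, 0.25])


def simulate_cross(spec: CrossSpec, state: str, seed: int = 0) -> pd.DataFrame:
    """Simulate one cross; returns one row per genotype class with delayed
    and wild-type counts."""
    if state not in spec.penetrance:
        raise ValueError(f"no penetrance table for state {state!r}")
    pen = spec.penetrance[state]
    rng = np.random.default_rng(seed)
    n_geno = rng.multinomial(spec.n_f2, _MENDEL)
    rows = []
    for g, n in zip(GENOTYPES, n_geno):
        delayed = int(rng.binomial(n, pen[g])) if n else 0
        rows.append({"genotype": g, "state": state, "n": int(n),
                     "n_delayed": delayed, "n_wildtype": int(n) - delayed})
    return pd.DataFrame(rows)


def cross_group(table: pd.DataFrame, genotype: str) -> CrossGroup:
    row = table[table.genotype == genotype].iloc[0]
    return CrossGroup(label=f"{row.state}:{genotype}",
                      n_delayed=int(row.n_delayed),
                      n_wildtype=int(row.n_wildtype))
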