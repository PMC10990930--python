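"""ChIP/input coverage simulation.

Input coverage is uniform Poisson over the reference; ChIP coverage is
Poisson with the same base rate multiplied by the enrichment factor inside
the planted intervals, and optionally by a global library-scale factor so
the two library sizes differ — the downstream ratio track must undo that
by normalizing each track to its own library size.
"""

from __future__ import annotations

import numpy as np

from ..silencing import CoverageTrack
from .config import ChipSpec

__all__ = ["simulate_chip"]


def simulate_chip(
    spec: ChipSpec,
    length: int,
    seed: int = 0,
    chip_scale: float = 1.0,
) -> tuple[CoverageTrack, CoverageTrack]:
    """Simulate a (ChIP, input) coverage pair over `length` positions of the
    reference named in the spec."""
    if spec.enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    rng = np.random.default_rng(seed)
    base = spec.depth / length
    input_vals = rng.poisson(base, size=length).astype(float)
    rate = np.full(length, base)
    for lo, hi in spec.enriched_intervals:
        if not 0 <= lo < hi <= length:
            raise ValueError("enriched interval outside the reference")
        rate[lo:hi] *= spec.enrichment
    chip_vals = rng.poisson(rate * chip_scale).astype(float)
    chip = CoverageTrack(reference=spec.reference, values=chip_vals,
                         norm="raw", library_size=float(chip_vals.sum()))
    inp = CoverageTrack(reference=spec.reference, values=input_vals,
                        norm="raw", library_size=float(input_vals.sum()))
    return chip, inp
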