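"""RT-qPCR Ct table simulation.

A transcript at relative level `fold` (case vs control) shifts the target
cycle threshold by -log2(fold)/log2(1 + efficiency); the housekeeping
channel has a constant expected Ct. Gaussian noise models replicate
scatter. With efficiency 1 and zero noise the downstream delta-delta-Ct
fold estimate recovers `fold` exactly.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import QpcrSpec

__all__ = ["simulate_qpcr"]


def simulate_qpcr(spec: QpcrSpec, seed: int = 0) -> pd.DataFrame:
    """Simulate Ct values; returns rows (condition, channel, replicate, ct)
    with conditions 'case' (expression x fold) and 'control'."""
    if spec.replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    shift = -math.log2(spec.fold) / math.log2(1 + spec.efficiency)
    rows = []
    for cond, target_ct in (("control", spec.baseline_ct),
                            ("case", spec.baseline_ct + shift)):
        for channel, mu in (("target", target_ct),
                            ("housekeeping", spec.housekeeping_ct)):
            for r in range(spec.replicates):
                ct = mu + (rng.normal(0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
                rows.append({"condition": cond, "channel": channel,
                             "replicate": r + 1, "ct": ct})
    return pd.DataFrame(rows)
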