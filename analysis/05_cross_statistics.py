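#!/usr/bin/env python
"""Score the published genetic crosses.

Count tables are reconstructed from the printed (percent delayed, n) pairs,
then each comparison gets a penetrance estimate with a 95% Agresti-Coull
interval and a two-sided Fisher's exact test.
"""

from pathlib import Path

import pandas as pd

from pirsil import io as pio
from pirsil.stats import agresti_coull_interval, counts_from_percent
from pirsil.workflows import PUBLISHED_CROSSES, cross_statistics

RESULTS = pio.ensure_dir(Path(__file__).resolve().parent.parent / "results")


def main() -> None:
    intervals = []
    for label, (pct, n) in PUBLISHED_CROSSES.items():
        g = counts_from_percent(pct, n)
        ci = agresti_coull_interval(g.n_delayed, g.n)
        intervals.append({"cross": label, "delayed": g.n_delayed, "n": g.n,
                          "penetrance": ci.estimate,
                          "ci95_lower": ci.lower, "ci95_upper": ci.upper})
    pd.DataFrame(intervals).to_csv(RESULTS / "cross_penetrance.tsv",
                                   sep="\t", index=False)

    stats = cross_statistics()
    stats.to_csv(RESULTS / "cross_statistics.tsv", sep="\t", index=False)
    with pd.option_context("display.width", 120):
        print(stats[["comparison", "table", "p_value"]].to_string(index=False))


if __name__ == "__main__":
    main()
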