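"""Cross-phenotype statistics: penetrance, Agresti–Coull binomial intervals,
exact two-sided Fisher tests, unpaired t-tests, ΔΔCt fold changes and CTCF.

These are the summary statistics used to score genetic crosses (delayed vs
wild-type F2 counts per genotype class), RT–qPCR tables and fluorescence ROI
measurements. Counts printed in figures as (percent, n) pairs can be turned
back into integer tables with :func:`counts_from_percent`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "CrossGroup",
    "BinomialCI",
    "FisherResult",
    "DdctResult",
    "penetrance",
    "counts_from_percent",
    "agresti_coull_interval",
    "fisher_exact_two_sided",
    "unpaired_t_test",
    "ddct_fold_change",
    "ctcf",
]


@dataclass(frozen=True)
class CrossGroup:
    """Delayed/wild-type counts for one genotype class of one cross."""

    label: str
    n_delayed: int
    n_wildtype: int

    def __post_init__(self) -> None:
        if self.n_delayed < 0 or self.n_wildtype < 0:
            raise ValueError(f"negative counts in group {self.label!r}")

    @property
    def n(self) -> int:
        return self.n_delayed + self.n_wildtype


@dataclass(frozen=True)
class BinomialCI:
    estimate: float
    centre: float
    lower: float
    upper: float
    level: float
    z: float


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    odds_ratio_kind: str
    table: tuple[tuple[int, int], tuple[int, int]]


@dataclass(frozen=True)
class DdctResult:
    dct_case: float
    dct_control: float
    ddct: float
    fold: float
    dct_case_sd: float = field(default=float("nan"))
    dct_control_sd: float = field(default=float("nan"))


def penetrance(group: CrossGroup) -> float:
    """Fraction of individuals in the group scored as delayed.

    For F2 non-carriers of a toxin–antidote cross this is the toxin's
    penetrance: the proportion of genotypically susceptible worms that are
    phenotypically affected.
    """
    if group.n == 0:
        raise ValueError(f"empty group {group.label!r}: penetrance undefined")
    return group.n_delayed / group.n


def counts_from_percent(percent: float, n: int) -> CrossGroup:
    """Reconstruct integer (delayed, wild-type) counts from a printed
    (percent delayed, n) pair, rounding percent×n to the nearest integer."""
    if not 0 <= percent <= 100:
        raise ValueError("percent outside [0, 100]")
    delayed = int(round(percent / 100.0 * n))
    return CrossGroup(label=f"{percent}%/{n}", n_delayed=delayed, n_wildtype=n - delayed)


def agresti_coull_interval(k: int, n: int, level: float = 0.95) -> BinomialCI:
    """Agresti–Coull (adjusted Wald) binomial confidence interval.

    With z the two-sided normal quantile for the requested level,
    ñ = n + z², p̃ = (k + z²/2)/ñ, and the interval is
    p̃ ± z·sqrt(p̃(1−p̃)/ñ), clipped to [0, 1].
    """
    if n <= 0 or not 0 <= k <= n:
        raise ValueError(f"invalid binomial data k={k}, n={n}")
    if not 0 < level < 1:
        raise ValueError("confidence level must be in (0, 1)")
    z = sps.norm.ppf(1 - (1 - level) / 2)
    n_adj = n + z * z
    centre = (k + z * z / 2) / n_adj
    half = z * math.sqrt(centre * (1 - centre) / n_adj)
    return BinomialCI(
        estimate=k / n,
        centre=centre,
        lower=max(0.0, centre - half),
        upper=min(1.0, centre + half),
        level=level,
        z=z,
    )


def _log_hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    """log P(table) for a 2x2 table with fixed margins, parameterized by the
    top-left cell a; rows sum to row1/row2 and the first column to col1."""
    n = row1 + row2
    return (
        gammaln(row1 + 1) - gammaln(a + 1) - gammaln(row1 - a + 1)
        + gammaln(row2 + 1) - gammaln(col1 - a + 1) - gammaln(row2 - (col1 - a) + 1)
        - (gammaln(n + 1) - gammaln(col1 + 1) - gammaln(n - col1 + 1))
    )


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher's exact test on the 2x2 table [[a, b], [c, d]].

    The two-sided p sums hypergeometric point probabilities over all tables
    with the observed margins whose probability does not exceed the observed
    table's by more than a relative factor of 1e-7 (the convention used by
    mainstream implementations). Computed in log space, so large tables are
    handled without overflow.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    if row1 == 0 or row2 == 0 or col1 == 0 or col2 == 0:
        # Degenerate margin: only one table is possible.
        import warnings

        warnings.warn("degenerate margin in 2x2 table; p = 1", stacklevel=2)
        p = 1.0
    else:
        lo = max(0, col1 - row2)
        hi = min(col1, row1)
        support = np.arange(lo, hi + 1)
        logp = np.array([_log_hypergeom_pmf(x, row1, row2, col1) for x in support])
        log_obs = _log_hypergeom_pmf(a, row1, row2, col1)
        keep = logp <= log_obs + math.log1p(1e-7)
        # logsumexp of the kept tables
        m = logp[keep].max()
        p = float(min(1.0, math.exp(m) * np.exp(logp[keep] - m).sum()))
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    return FisherResult(p_value=p, odds_ratio=odds, odds_ratio_kind="sample",
                        table=((a, b), (c, d)))


def fisher_groups(x: CrossGroup, y: CrossGroup) -> FisherResult:
    """Fisher test comparing the delayed fractions of two cross groups."""
    return fisher_exact_two_sided(x.n_delayed, x.n_wildtype, y.n_delayed, y.n_wildtype)


def unpaired_t_test(x, y, welch: bool = False) -> tuple[float, float, float]:
    """Two-sided unpaired t-test; Student (pooled variance) by default,
    Welch when requested. Returns (t, degrees of freedom, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two observations per sample")
    if x.std() == 0 and y.std() == 0 and x.mean() == y.mean():
        df = x.size + y.size - 2
        return 0.0, float(df), 1.0
    res = sps.ttest_ind(x, y, equal_var=not welch)
    if welch:
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        nx, ny = x.size, y.size
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    else:
        df = x.size + y.size - 2
    return float(res.statistic), float(df), float(res.pvalue)


def ddct_fold_change(
    ct_target_case,
    ct_housekeeping_case,
    ct_target_control,
    ct_housekeeping_control,
) -> DdctResult:
    """ΔΔCt relative quantification against a housekeeping gene.

    ΔCt = mean Ct(target) − mean Ct(housekeeping) per condition;
    ΔΔCt = ΔCt(case) − ΔCt(control); fold = 2^(−ΔΔCt).
    """
    arrs = [np.asarray(v, dtype=float) for v in (
        ct_target_case, ct_housekeeping_case, ct_target_control, ct_housekeeping_control)]
    if any(a.size == 0 for a in arrs):
        raise ValueError("every Ct channel needs at least one replicate")
    tc, hc, tk, hk = arrs
    dct_case = float(tc.mean() - hc.mean())
    dct_control = float(tk.mean() - hk.mean())
    ddct = dct_case - dct_control
    return DdctResult(
        dct_case=dct_case,
        dct_control=dct_control,
        ddct=ddct,
        fold=float(2.0 ** (-ddct)),
        dct_case_sd=float(np.sqrt(tc.var(ddof=1) + hc.var(ddof=1))) if tc.size > 1 and hc.size > 1 else float("nan"),
        dct_control_sd=float(np.sqrt(tk.var(ddof=1) + hk.var(ddof=1))) if tk.size > 1 and hk.size > 1 else float("nan"),
    )


def ctcf(integrated_density: float, area: float, mean_background: float) -> float:
    """Corrected total cell fluorescence of an ROI:
    integrated density − area × mean background. May be negative."""
    if area < 0:
        raise ValueError("area must be non-negative")
    return integrated_density - area * mean_background
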