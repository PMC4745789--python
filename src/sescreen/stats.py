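"""Statistical tests used across the enrichment and screening modules.

The Fisher exact test is computed with exact integer arithmetic over the
hypergeometric support (two-sided: sum of point probabilities no larger
than the observed table's). Welch's t test and the Mann-Whitney U test
delegate to scipy behind this module's surface.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import stats as sps

#: Display-only floor used in reports, matching the convention of printing
#: vanishingly small p-values as "< 2.2e-16". Stored values are never floored.
P_DISPLAY_FLOOR = 2.2e-16


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = region class, columns = feature +/-."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be nonnegative")
        if self.total == 0:
            raise ValueError("contingency table must have total > 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def row_margins(self):
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self):
        return (self.a + self.c, self.b + self.d)

    def as_list(self):
        return [[self.a, self.b], [self.c, self.d]]


@dataclass(frozen=True)
class EnrichmentResult:
    """A named test outcome with its statistic, p-value, and summaries."""

    name: str
    p_value: Optional[float]
    statistic: Optional[float] = None
    odds_ratio: Optional[float] = None
    details: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value must lie in [0, 1]")

    def display_p(self) -> str:
        if self.p_value is None:
            return "NA"
        if self.p_value < P_DISPLAY_FLOOR:
            return f"< {P_DISPLAY_FLOOR:g}"
        return f"{self.p_value:.4g}"


def sample_odds_ratio(table: ContingencyTable2x2) -> float:
    """Cross-product odds ratio (a·d)/(b·c); +inf when b·c = 0 < a·d."""
    ad, bc = table.a * table.d, table.b * table.c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


def fisher_exact(table: ContingencyTable2x2) -> EnrichmentResult:
    """Two-sided Fisher exact test on a 2x2 table.

    The p-value is the exact sum of hypergeometric point probabilities that
    do not exceed the observed table's probability, with all margins fixed.
    Computed in integer arithmetic, so ties in point probability are exact.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    N = table.total
    K = a + b  # row-1 margin
    n = a + c  # col-1 margin
    lo = max(0, K + n - N)
    hi = min(K, n)
    numerators = [math.comb(K, x) * math.comb(N - K, n - x) for x in range(lo, hi + 1)]
    observed = numerators[a - lo]
    total = sum(numerators)
    p = sum(v for v in numerators if v <= observed) / total
    return EnrichmentResult(
        name="fisher_exact",
        p_value=min(p, 1.0),
        odds_ratio=sample_odds_ratio(table),
        details={"table": table.as_list()},
    )


def welch_t_test(x: Sequence[float], y: Sequence[float]) -> EnrichmentResult:
    """Two-sided Welch t test (unequal variances)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("welch_t_test requires >= 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("welch_t_test: both samples are degenerate (zero variance)")
    res = sps.ttest_ind(x, y, equal_var=False)
    sx2, sy2 = vx / len(x), vy / len(y)
    df = (sx2 + sy2) ** 2 / (sx2**2 / (len(x) - 1) + sy2**2 / (len(y) - 1))
    return EnrichmentResult(
        name="welch_t",
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        details={
            "df": float(df),
            "mean_x": float(x.mean()),
            "mean_y": float(y.mean()),
            "n_x": int(len(x)),
            "n_y": int(len(y)),
        },
    )


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> EnrichmentResult:
    """Mann-Whitney U test with ties receiving half credit.

    Exact by enumeration of all C(nx+ny, nx) labelings when the pooled
    sample has at most 16 observations and no ties; otherwise the normal
    approximation with continuity and tie correction.
    """
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 16 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return EnrichmentResult(
        name="mann_whitney",
        p_value=float(res.pvalue),
        statistic=float(res.statistic),
        details={
            "method": method,
            "n_x": int(len(x)),
            "n_y": int(len(y)),
            "median_x": float(np.median(x)),
            "median_y": float(np.median(y)),
        },
    )
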