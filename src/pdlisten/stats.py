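"""Two-sample significance tests on dialogue-level mention indicators.

SOV comparisons are framed as independent-samples t-tests on the 0/1
indicator vectors (does this dialogue mention the unit?), i.e. a Welch t
with unpooled variances and Welch–Satterthwaite degrees of freedom.  At the
corpus sizes involved this is numerically indistinguishable from the
unpooled two-proportion z test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as sps

from .metrics import SOVRow


@dataclass(frozen=True)
class ProportionTestResult:
    x1: int
    n1: int
    x2: int
    n2: int
    statistic: float
    df: float
    p_value: float

    @property
    def estimate1(self) -> float:
        return self.x1 / self.n1

    @property
    def estimate2(self) -> float:
        return self.x2 / self.n2


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> ProportionTestResult:
    """Welch t-test on two Bernoulli samples given their counts.

    Equivalent to ``scipy.stats.ttest_ind(a, b, equal_var=False)`` on the
    expanded 0/1 vectors, but computed in closed form from the counts.  When
    both samples are constant and equal the statistic is 0 and p is 1.
    """
    for x, n, side in ((x1, n1, "first"), (x2, n2, "second")):
        if n < 2:
            raise ValueError(f"{side} sample needs n >= 2, got {n}")
        if not 0 <= x <= n:
            raise ValueError(f"{side} sample has x={x} outside [0, {n}]")

    p1, p2 = x1 / n1, x2 / n2
    # unbiased sample variance of a 0/1 vector with mean p
    s1 = p1 * (1.0 - p1) * n1 / (n1 - 1)
    s2 = p2 * (1.0 - p2) * n2 / (n2 - 1)
    a, b = s1 / n1, s2 / n2
    se2 = a + b
    if se2 == 0.0:
        if p1 == p2:
            return ProportionTestResult(x1, n1, x2, n2, 0.0, float(n1 + n2 - 2), 1.0)
        statistic = math.inf if p1 > p2 else -math.inf
        return ProportionTestResult(x1, n1, x2, n2, statistic, float(n1 + n2 - 2), 0.0)
    statistic = (p1 - p2) / math.sqrt(se2)
    df = se2**2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))
    p_value = 2.0 * float(sps.t.sf(abs(statistic), df))
    return ProportionTestResult(x1, n1, x2, n2, statistic, df, p_value)


def trend_test(sov_row_start: SOVRow, sov_row_end: SOVRow) -> ProportionTestResult:
    """Compare one unit's SOV between two years (independent samples)."""
    if sov_row_start.unit != sov_row_end.unit:
        raise ValueError(
            f"trend test requires the same unit, got {sov_row_start.unit.label!r} "
            f"and {sov_row_end.unit.label!r}"
        )
    if sov_row_start.year == sov_row_end.year:
        raise ValueError(f"trend test requires two different years, got {sov_row_start.year}")
    return two_proportion_test(
        sov_row_start.numerator,
        sov_row_start.denominator,
        sov_row_end.numerator,
        sov_row_end.denominator,
    )


def between_group_test(sov_row_a: SOVRow, sov_row_b: SOVRow) -> ProportionTestResult:
    """Compare two units' SOV within the same year (independent samples, as
    in the study design; the indicators in fact share the dialogue set)."""
    if sov_row_a.year != sov_row_b.year:
        raise ValueError(
            f"between-group test requires the same year, got {sov_row_a.year} "
            f"and {sov_row_b.year}"
        )
    return two_proportion_test(
        sov_row_a.numerator,
        sov_row_a.denominator,
        sov_row_b.numerator,
        sov_row_b.denominator,
    )
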