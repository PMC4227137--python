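"""2x2 association of signature calls with parity.

The table orientation is fixed: rows are parity (nulliparous, parous),
columns are the Creighton call (negative, positive):

    a = nulliparous & negative    b = nulliparous & positive
    c = parous & negative         d = parous & positive

The cross-product odds ratio OR = (a*d)/(b*c) is the odds of a positive
signature call among parous relative to nulliparous women, identical to the
logistic-regression MLE for a single binary covariate. The 95% CI is the
Wald interval exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)). The p-value
uses Pearson's chi-square (1 df, no continuity correction) unless any
expected cell count is below five, in which case the two-sided Fisher exact
test (sum of hypergeometric probabilities not exceeding the observed
table's) is used; that p is computed by exact rational enumeration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats

from .errors import ZeroCellError
from ._utils import parous_mask

Z975 = stats.norm.ppf(0.975)


@dataclass(frozen=True)
class ContingencyTable:
    """Counts in the fixed parity x call orientation described above."""

    a: int  # nulliparous, negative
    b: int  # nulliparous, positive
    c: int  # parous, negative
    d: int  # parous, positive

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def has_zero_cell(self) -> bool:
        return 0 in self.cells

    @classmethod
    def from_calls(cls, calls, parity) -> "ContingencyTable":
        """Cross-tabulate Creighton calls ('positive'/'negative') with parity."""
        calls = np.asarray(calls)
        par = parous_mask(parity)
        if len(calls) != len(par):
            raise ValueError("calls and parity labels differ in length")
        pos = calls == "positive"
        return cls(
            a=int((~par & ~pos).sum()),
            b=int((~par & pos).sum()),
            c=int((par & ~pos).sum()),
            d=int((par & pos).sum()),
        )


def _corrected_cells(t: ContingencyTable, haldane: bool) -> tuple[float, float, float, float]:
    if t.has_zero_cell():
        if not haldane:
            raise ZeroCellError(
                f"table {t.cells} has an empty cell; pass haldane=True to add 0.5 "
                "to every cell (Haldane-Anscombe correction)"
            )
        return tuple(v + 0.5 for v in t.cells)  # type: ignore[return-value]
    return tuple(float(v) for v in t.cells)  # type: ignore[return-value]


def odds_ratio(t: ContingencyTable, haldane: bool = False) -> float:
    a, b, c, d = _corrected_cells(t, haldane)
    return (a * d) / (b * c)


def wald_ci(
    t: ContingencyTable, level: float = 0.95, haldane: bool = False
) -> tuple[float, float]:
    a, b, c, d = _corrected_cells(t, haldane)
    z = stats.norm.ppf(0.5 + level / 2)
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def wald_z_pvalue(t: ContingencyTable, haldane: bool = False) -> float:
    """Two-sided p from the Wald z statistic on ln OR (reported alongside)."""
    a, b, c, d = _corrected_cells(t, haldane)
    z = math.log((a * d) / (b * c)) / math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(2 * stats.norm.sf(abs(z)))


def expected_counts(t: ContingencyTable) -> np.ndarray:
    n = t.total
    rows = np.array([t.a + t.b, t.c + t.d], dtype=float)
    cols = np.array([t.a + t.c, t.b + t.d], dtype=float)
    return np.outer(rows, cols) / n


def chi2_statistic(t: ContingencyTable) -> float:
    """Pearson chi-square, 1 df, no continuity correction (closed form)."""
    a, b, c, d = (float(v) for v in t.cells)
    n = t.total
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0:
        return float("nan")
    return n * (a * d - b * c) ** 2 / denom


def chi2_pvalue(t: ContingencyTable) -> float:
    stat = chi2_statistic(t)
    if math.isnan(stat):
        return float("nan")
    return float(stats.chi2.sf(stat, df=1))


def fisher_pvalue(t: ContingencyTable) -> float:
    """Two-sided Fisher exact p by exact rational enumeration.

    Sums the hypergeometric probabilities of all tables sharing the observed
    margins whose probability does not exceed the observed table's; the
    comparison is exact (Fraction arithmetic), so the result matches
    brute-force enumeration to machine precision.
    """
    r1, r2 = t.a + t.b, t.c + t.d
    c1 = t.a + t.c
    n = t.total
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return float("nan")
    denom = math.comb(n, c1)
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    pmf = {
        k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = pmf[t.a]
    return float(sum(p for p in pmf.values() if p <= p_obs))


def association_test(t: ContingencyTable) -> tuple[float, str, float]:
    """(p_value, test_used, min_expected_count) by the expected-count rule.

    Fisher's exact test when the smallest expected cell count is below five,
    Pearson chi-square otherwise. A zero margin leaves the p undefined
    (NaN, test 'undefined').
    """
    exp = expected_counts(t)
    min_exp = float(exp.min())
    rows = (t.a + t.b, t.c + t.d)
    cols = (t.a + t.c, t.b + t.d)
    if 0 in rows or 0 in cols:
        return float("nan"), "undefined", min_exp
    if min_exp < 5:
        return fisher_pvalue(t), "fisher", min_exp
    return chi2_pvalue(t), "chi2", min_exp


@dataclass
class AssociationResult:
    """OR with Wald CI and the test p-value for one 2x2 comparison."""

    table: ContingencyTable
    or_estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    test_used: str
    min_expected_count: float
    p_wald: float

    def to_dict(self) -> dict:
        return {
            "counts": list(self.table.cells),
            "or": round(self.or_estimate, 2),
            "ci_low": round(self.ci_low, 2),
            "ci_high": round(self.ci_high, 2),
            "p_value": self.p_value,
            "test_used": self.test_used,
            "min_expected_count": self.min_expected_count,
            "p_wald": self.p_wald,
        }


def associate(
    t: ContingencyTable, level: float = 0.95, haldane: bool = False
) -> AssociationResult:
    """Bundle OR, Wald CI and the chi-square/Fisher p for one table."""
    p, test_used, min_exp = association_test(t)
    orr = odds_ratio(t, haldane)
    lo, hi = wald_ci(t, level, haldane)
    return AssociationResult(
        table=t,
        or_estimate=orr,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        test_used=test_used,
        min_expected_count=min_exp,
        p_wald=wald_z_pvalue(t, haldane),
    )
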