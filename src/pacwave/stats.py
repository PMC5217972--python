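"""Proportions, 2x2 chi-square, exact binomial test, condition comparison.

The handful of statistics the pipeline reports.  P-values below the
double-precision convention 2.2e-16 are reported as the string
``"< 2.2e-16"`` alongside the floored numeric value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

P_FLOOR = 2.2e-16


@dataclass
class ConditionSummary:
    """Host-read burden of one experimental condition."""

    label: str  # induction | infection
    host_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.host_reads > self.total_reads:
            raise ValueError("host_reads cannot exceed total_reads")

    @property
    def host_fraction(self) -> float:
        return self.host_reads / self.total_reads

    @property
    def ci95(self) -> tuple[float, float]:
        return proportion_with_ci(self.host_reads, self.total_reads)[1]


def proportion_with_ci(successes: int, total: int, level: float = 0.95):
    """Point estimate and Wilson score interval.

    Returns ``(fraction, (low, high))``.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= successes <= total:
        raise ValueError("successes must lie in [0, total]")
    frac = successes / total
    lo, hi = proportion_confint(successes, total, alpha=1 - level, method="wilson")
    # guard floating-point droop at the boundaries: the interval must
    # contain the point estimate and stay inside [0, 1]
    lo = max(0.0, min(float(lo), frac))
    hi = min(1.0, max(float(hi), frac))
    return frac, (lo, hi)


def chisq_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float, str]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)); the 1-df upper-tail
    p-value is erfc(sqrt(x/2)).  Returns ``(statistic, p, printed_p)``
    where ``printed_p`` applies the "< 2.2e-16" underflow convention.
    """
    for v in (a, b, c, d):
        if v < 0:
            raise ValueError("counts must be non-negative")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("both margins must be positive")
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p = math.erfc(math.sqrt(stat / 2.0))
    p = max(p, 5e-324)
    printed = f"< {P_FLOOR:.1e}" if p < P_FLOOR else f"{p:.3g}"
    return stat, p, printed


def binom_test_two_sided(k: int, n: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p: sum of P(X=i) over i with P(X=i) <= P(X=k)."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)


def compare_conditions(induction: ConditionSummary, infection: ConditionSummary) -> dict:
    """Side-by-side host-DNA burden: fractions, CIs, ratio, chi-square."""
    f_ind, ci_ind = proportion_with_ci(induction.host_reads, induction.total_reads)
    f_inf, ci_inf = proportion_with_ci(infection.host_reads, infection.total_reads)
    stat, p, printed = chisq_2x2(
        induction.host_reads, induction.total_reads - induction.host_reads,
        infection.host_reads, infection.total_reads - infection.host_reads,
    )
    if infection.host_reads == 0:
        ratio = None
        flag = "ratio undefined: no host reads in infection condition"
    else:
        ratio = f_ind / f_inf
        flag = ("induction excess" if ratio > 1
                else "infection excess" if ratio < 1 else "no excess")
    return {
        "induction": {"host_reads": induction.host_reads,
                      "total_reads": induction.total_reads,
                      "host_fraction": f_ind, "host_pct": round(100 * f_ind, 1),
                      "ci95": ci_ind},
        "infection": {"host_reads": infection.host_reads,
                      "total_reads": infection.total_reads,
                      "host_fraction": f_inf, "host_pct": round(100 * f_inf, 1),
                      "ci95": ci_inf},
        "ratio": ratio,
        "chi2": stat,
        "p_value": p,
        "p_printed": printed,
        "flag": flag,
    }
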