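"""Carrier-frequency tabulation and exact 2x2 tests.

Carrier counts per study group are compared pairwise (cancer group vs
control group) with the classical two-sided Fisher exact test: the
p-value is the total conditional hypergeometric probability of all
tables with the observed margins whose probability does not exceed the
observed table's (a relative tie tolerance of 1e-7 guards against
floating-point near-ties). Familial groups use families as the
denominator, sporadic and control groups use participants.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache
from math import exp, log, sqrt

import numpy as np
from scipy.stats import hypergeom

from .types import CarrierTable, Cohort

_TIE_REL_TOL = 1e-7


@lru_cache(maxsize=200_000)
def _fisher_p(a: int, b: int, c: int, d: int) -> float:
    n_total = a + b + c + d
    k_carriers = a + c
    n_row = a + b
    if k_carriers == 0 or n_total == 0:
        return 1.0
    lo = max(0, n_row + k_carriers - n_total)
    hi = min(n_row, k_carriers)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n_total, k_carriers, n_row)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + _TIE_REL_TOL)].sum())
    return min(p, 1.0)


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table [[a, b], [c, d]].

    Rows are the two groups, columns carrier / non-carrier. Returns 1.0
    when the carrier margin is empty. Raises on negative cells.
    """
    (a, b), (c, d) = table
    cells = (int(a), int(b), int(c), int(d))
    if any(x < 0 for x in cells):
        raise ValueError(f"negative cell in 2x2 table: {table}")
    return _fisher_p(*cells)


def fisher_exact_one_sided_greater(table) -> float:
    """One-sided p for enrichment of carriers in the first row."""
    (a, b), (c, d) = table
    a, b, c, d = int(a), int(b), int(c), int(d)
    if any(x < 0 for x in (a, b, c, d)):
        raise ValueError("negative cell in 2x2 table")
    n_total = a + b + c + d
    k_carriers = a + c
    if k_carriers == 0 or n_total == 0:
        return 1.0
    return float(hypergeom.sf(a - 1, n_total, k_carriers, a + b))


def exact_two_arm_rejection_probability(
    n_case: int,
    n_control: int,
    p_case: float,
    p_control: float,
    alpha: float = 0.05,
    tail_eps: float = 1e-10,
) -> float:
    """Exact probability that the two-sided Fisher test rejects at
    ``alpha`` when carrier counts are independent binomials per arm.

    Summing the joint binomial pmf over the (truncated) count grid
    gives the test's exact size when ``p_case == p_control`` and its
    exact power otherwise; the truncation error is below ``tail_eps``
    per arm.
    """
    from scipy.stats import binom

    a_hi = int(binom.ppf(1.0 - tail_eps, n_case, p_case)) + 2
    c_hi = int(binom.ppf(1.0 - tail_eps, n_control, p_control)) + 2
    pa = binom.pmf(np.arange(a_hi), n_case, p_case)
    pc = binom.pmf(np.arange(c_hi), n_control, p_control)
    total = 0.0
    for a in range(a_hi):
        for c in range(c_hi):
            if _fisher_p(a, n_case - a, c, n_control - c) < alpha:
                total += pa[a] * pc[c]
    return float(total)


@dataclass(frozen=True)
class CarrierFrequency:
    """A carrier fraction with its publication-style percent string."""

    carriers: int
    denominator: int
    fraction: float
    percent: str  # 1 decimal place, round half up

    def __str__(self) -> str:
        return f"{self.carriers}/{self.denominator} ({self.percent})"


def carrier_frequency(carriers: int, denominator: int) -> CarrierFrequency:
    """Carrier fraction with the percent formatted to 1 d.p. (half-up)."""
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    if not 0 <= carriers <= denominator:
        raise ValueError(f"carriers {carriers} outside [0, {denominator}]")
    fraction = carriers / denominator
    percent = Decimal(carriers * 100) / Decimal(denominator)
    formatted = str(percent.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return CarrierFrequency(
        carriers=carriers, denominator=denominator, fraction=fraction, percent=formatted
    )


@dataclass(frozen=True)
class ContingencyResult:
    """One pairwise case/control carrier comparison for one variant."""

    variant_id: str
    case_group: str
    control_group: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p_two_sided: float
    carrier_freq_case: CarrierFrequency
    carrier_freq_control: CarrierFrequency
    odds_ratio: float | None
    or_ci95: tuple[float, float] | None


def _odds_ratio_woolf(a: int, b: int, c: int, d: int) -> tuple[float | None, tuple | None]:
    # sample OR with Woolf (log) 95% CI; undefined whenever any cell is 0
    if min(a, b, c, d) == 0:
        return None, None
    or_ = (a * d) / (b * c)
    se = sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return or_, (exp(log(or_) - 1.959963984540054 * se), exp(log(or_) + 1.959963984540054 * se))


def contingency_test(
    variant_id: str,
    case_group: str,
    control_group: str,
    case_carriers: int,
    case_denominator: int,
    control_carriers: int,
    control_denominator: int,
) -> ContingencyResult:
    a, b = case_carriers, case_denominator - case_carriers
    c, d = control_carriers, control_denominator - control_carriers
    if b < 0 or d < 0:
        raise ValueError("carriers exceed denominator")
    or_, ci = _odds_ratio_woolf(a, b, c, d)
    return ContingencyResult(
        variant_id=variant_id,
        case_group=case_group,
        control_group=control_group,
        table=((a, b), (c, d)),
        p_two_sided=fisher_exact_two_sided(((a, b), (c, d))),
        carrier_freq_case=carrier_frequency(a, case_denominator),
        carrier_freq_control=carrier_frequency(c, control_denominator),
        odds_ratio=or_,
        or_ci95=ci,
    )


def pairwise_case_control_tests(
    cohort: Cohort,
    carrier_table: CarrierTable | None = None,
    pairs: list[tuple[str, str]] | None = None,
    variants: list[str] | None = None,
) -> list[ContingencyResult]:
    """One Fisher test per (variant, case group, control group).

    Denominators follow each group's counting unit (families for
    familial groups). By default every case group is paired with every
    control group and every variant in the carrier table is tested.
    """
    table = carrier_table if carrier_table is not None else cohort.carrier_table
    if pairs is None:
        from .types import Role

        cases = [g.name for g in cohort.groups if g.role is Role.CASE]
        controls = [g.name for g in cohort.groups if g.role is Role.CONTROL]
        pairs = [(case, control) for case in cases for control in controls]
    variant_ids = variants if variants is not None else table.variants()

    results: list[ContingencyResult] = []
    for variant_id in variant_ids:
        for case_name, control_name in pairs:
            case = cohort.group(case_name)
            control = cohort.group(control_name)
            results.append(
                contingency_test(
                    variant_id,
                    case_name,
                    control_name,
                    table.count(case_name, variant_id),
                    case.n_units,
                    table.count(control_name, variant_id),
                    control.n_units,
                )
            )
    return results
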