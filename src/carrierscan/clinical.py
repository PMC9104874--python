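"""Clinico-pathological summaries for variant carriers.

Descriptive statistics of age at diagnosis and survival months,
proportions below an age cut-off, and two-group comparisons with an
unpaired Student's t-test (pooled variance by default, matching the
plain "unpaired t-test" convention; Welch's correction is available
behind a flag) with the 95% confidence interval of the mean
difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from math import sqrt

import numpy as np
from scipy import stats as sps


class VitalStatus(str, Enum):
    DECEASED_OC = "deceased_oc"
    ALIVE = "alive"
    OTHER = "other"
    MISSING = "missing"


@dataclass(frozen=True)
class ClinicalRecord:
    """Clinical features of one carrier."""

    carrier_id: str
    variant_id: str
    age_at_diagnosis: float
    survival_months: float | None = None
    vital_status: VitalStatus = VitalStatus.MISSING
    histopathology: str = ""

    def __post_init__(self) -> None:
        if self.age_at_diagnosis <= 0:
            raise ValueError("age_at_diagnosis must be positive")
        if self.survival_months is not None and self.survival_months < 0:
            raise ValueError("survival_months must be non-negative")


@dataclass(frozen=True)
class Summary:
    n: int
    mean: float
    median: float
    min: float
    max: float
    sd: float | None  # sample SD (n-1); None when n < 2


def summarize(values: list[float]) -> Summary:
    """Mean, median, range and sample standard deviation (n-1)."""
    if len(values) == 0:
        raise ValueError("cannot summarize an empty list")
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1)) if arr.size >= 2 else None
    return Summary(
        n=int(arr.size),
        mean=float(arr.mean()),
        median=float(np.median(arr)),
        min=float(arr.min()),
        max=float(arr.max()),
        sd=sd,
    )


def proportion_below(values: list[float], cutoff: float) -> tuple[int, int, int]:
    """(count, total, percent) of values strictly below the cutoff.

    "Diagnosed before age 60" is a strict inequality; the percent is
    rounded half-up to an integer, prose style.
    """
    if len(values) == 0:
        raise ValueError("cannot compute a proportion of an empty list")
    count = sum(1 for v in values if v < cutoff)
    total = len(values)
    percent = int(
        (Decimal(count * 100) / Decimal(total)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )
    return count, total, percent


@dataclass(frozen=True)
class TTestResult:
    t: float
    p_two_sided: float
    mean_diff: float  # mean(a) - mean(b)
    ci95: tuple[float, float]
    df: float
    welch: bool


def unpaired_t_test(
    group_a: list[float], group_b: list[float], welch: bool = False
) -> TTestResult:
    """Two-sided unpaired t-test with 95% CI of the mean difference.

    Pooled-variance Student's test by default; ``welch=True`` uses the
    Welch-Satterthwaite correction. Both groups with zero variance is
    degenerate: equal means return t=0, p=1; unequal means raise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    mean_diff = float(a.mean() - b.mean())

    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if mean_diff == 0.0:
            return TTestResult(
                t=0.0, p_two_sided=1.0, mean_diff=0.0, ci95=(0.0, 0.0),
                df=float(a.size + b.size - 2), welch=welch,
            )
        raise ValueError("zero variance in both groups with unequal means is degenerate")

    res = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        se = sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    else:
        df = a.size + b.size - 2
        sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
        se = sqrt(sp2 * (1 / a.size + 1 / b.size))
    t_crit = float(sps.t.ppf(0.975, df))
    return TTestResult(
        t=float(res.statistic),
        p_two_sided=float(res.pvalue),
        mean_diff=mean_diff,
        ci95=(mean_diff - t_crit * se, mean_diff + t_crit * se),
        df=float(df),
        welch=welch,
    )


def compare_carrier_groups(
    records_a: list[ClinicalRecord],
    records_b: list[ClinicalRecord],
    attribute: str = "age_at_diagnosis",
    welch: bool = False,
) -> dict:
    """Summaries and t-test for one clinical attribute across two carrier groups."""
    values_a = [getattr(r, attribute) for r in records_a if getattr(r, attribute) is not None]
    values_b = [getattr(r, attribute) for r in records_b if getattr(r, attribute) is not None]
    return {
        "attribute": attribute,
        "group_a": summarize(values_a),
        "group_b": summarize(values_b),
        "t_test": unpaired_t_test(values_a, values_b, welch=welch),
    }
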