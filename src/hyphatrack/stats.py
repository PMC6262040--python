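"""Condition-level aggregation and two-variant t-tests.

Chamber- and well-level metrics are grouped by medium condition (CM, CAS,
AA20, AA08, AA04, AA00 in the reference experiment), summarized as
n/mean/SD, and compared pairwise with both the pooled-variance (Student)
and the unequal-variance (Welch) two-sided t-test.  Both variants are
always reported; the significance call (p < 0.05) uses the Welch p-value
as the robust default.  No multiple-testing correction is applied by
default (raw pairwise p-values); a Bonferroni-adjusted column is
available on request.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps


@dataclass
class ConditionSummary:
    medium_id: str
    metric: str
    n: int
    mean: float
    sd: float
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class TTestResult:
    metric: str
    condition_a: str
    condition_b: str
    student_t: float
    student_df: float
    student_p: float
    welch_t: float
    welch_df: float
    welch_p: float
    significant: bool
    bonferroni_p: float | None = None


def summarize_condition(values, medium_id: str,
                        metric: str = "") -> ConditionSummary:
    """n, mean and sample SD (n-1 denominator) of one condition's values."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no values to summarize")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite value in condition data")
    flags = []
    if values.size == 1:
        sd = 0.0
        flags.append("no variance")
    else:
        sd = float(values.std(ddof=1))
    return ConditionSummary(medium_id=medium_id, metric=metric,
                            n=int(values.size), mean=float(values.mean()),
                            sd=sd, qc_flags=flags)


def compare_conditions(values_a, values_b, metric: str = "",
                       condition_a: str = "a", condition_b: str = "b",
                       alpha: float = 0.05,
                       n_comparisons: int | None = None) -> TTestResult:
    """Two-sided Student (pooled) and Welch t-tests on two samples."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need n >= 2 for a t-test")
    student_df = float(a.size + b.size - 2)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        # degenerate contract: equal means -> t=0, p=1; else p -> 0
        if np.isclose(a.mean(), b.mean()):
            st = wt = 0.0
            sp = wp = 1.0
        else:
            st = wt = np.inf if a.mean() > b.mean() else -np.inf
            sp = wp = 0.0
        welch_df = 1.0
    else:
        st, sp = sps.ttest_ind(a, b, equal_var=True)
        wt, wp = sps.ttest_ind(a, b, equal_var=False)
        na, nb = a.size, b.size
        num = (va / na + vb / nb) ** 2
        den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        welch_df = max(1.0, float(num / den)) if den > 0 else 1.0
    bonf = None
    if n_comparisons:
        bonf = float(min(1.0, wp * n_comparisons))
    return TTestResult(
        metric=metric, condition_a=condition_a, condition_b=condition_b,
        student_t=float(st), student_df=student_df, student_p=float(sp),
        welch_t=float(wt), welch_df=float(welch_df), welch_p=float(wp),
        significant=bool(wp < alpha), bonferroni_p=bonf,
    )


def germination_fraction(germinated_flags) -> float:
    """Fraction of chambers whose spore germinated, in [0, 1]."""
    flags = np.asarray(list(germinated_flags), dtype=bool)
    if flags.size == 0:
        raise ValueError("no chambers supplied")
    return float(flags.mean())
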