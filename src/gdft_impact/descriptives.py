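"""Group-level descriptive summaries and two-group comparisons.

Patients are split into those with one or more in-hospital postoperative
complications and those without any. Costs are compared with a two-sample
t test (Welch by default — the group SDs differ severalfold), length of
stay with the Wilcoxon rank-sum test, and 30-day readmission with a Pearson
chi-squared test on the 2x2 table. Cost statistics use cost-valid records
only; LOS and readmission use every record.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord, to_dataframe

WITH = "with_complications"
WITHOUT = "without_complications"
OVERALL = "overall"


class InsufficientDataError(ValueError):
    """A group is too small (or too degenerate) for the requested test."""


@dataclass
class CohortSummary:
    """Descriptives for one complication group within one scope.

    ``scope`` is ``"overall"`` or a procedure label. Statistics that are
    undefined for the group size (SD of one record, quantiles of none) are
    ``None``. Rates are percentages.
    """

    group: str
    scope: str
    n: int
    n_cost_valid: int
    morbidity_rate: float | None
    cost_mean: float | None
    cost_sd: float | None
    los_median: float | None
    los_q25: float | None
    los_q75: float | None
    readmit_rate: float | None


@dataclass
class ComparisonResult:
    quantity: str
    test: str
    statistic: float
    p_value: float


def _group_summary(df: pd.DataFrame, group: str, scope: str,
                   morbidity_rate: float | None) -> CohortSummary:
    n = len(df)
    valid = df[df["cost_valid"]]
    costs = valid["cost"].to_numpy(dtype=float)
    if n == 0:
        return CohortSummary(group, scope, 0, 0, morbidity_rate,
                             None, None, None, None, None, None)
    los = df["los"].to_numpy(dtype=float)
    q25, med, q75 = np.percentile(los, [25, 50, 75])  # linear interpolation
    return CohortSummary(
        group=group, scope=scope, n=n, n_cost_valid=len(valid),
        morbidity_rate=morbidity_rate,
        cost_mean=float(costs.mean()) if len(costs) >= 1 else None,
        cost_sd=float(costs.std(ddof=1)) if len(costs) >= 2 else None,
        los_median=float(med), los_q25=float(q25), los_q75=float(q75),
        readmit_rate=float(100 * df["readmit_30d"].mean()),
    )


def summarize(records: Sequence[PatientRecord], by_procedure: bool = False) -> list[CohortSummary]:
    """One :class:`CohortSummary` per complication group (x procedure).

    The morbidity rate reported on each pair of summaries is
    ``100 * n_with / (n_with + n_without)`` within the scope.
    """
    if not records:
        raise InsufficientDataError("empty cohort")
    df = to_dataframe(records)

    def scope_pair(sub: pd.DataFrame, scope: str) -> list[CohortSummary]:
        with_df = sub[sub["complication"]]
        without_df = sub[~sub["complication"]]
        morbidity = 100.0 * len(with_df) / len(sub)
        return [_group_summary(with_df, WITH, scope, morbidity),
                _group_summary(without_df, WITHOUT, scope, morbidity)]

    out = scope_pair(df, OVERALL)
    if by_procedure:
        for proc in df["procedure"].unique():
            out.extend(scope_pair(df[df["procedure"] == proc], proc))
    return out


def summaries_to_frame(summaries: Sequence[CohortSummary]) -> pd.DataFrame:
    """Flat table of summaries (one row per group x scope) for CSV export."""
    return pd.DataFrame([s.__dict__ for s in summaries])


def _split_costs(records: Sequence[PatientRecord]) -> tuple[np.ndarray, np.ndarray]:
    with_c = np.array([r.cost for r in records if r.complication and r.cost_valid], dtype=float)
    without_c = np.array([r.cost for r in records if not r.complication and r.cost_valid], dtype=float)
    return with_c, without_c


def compare_costs(records: Sequence[PatientRecord], pooled: bool = False) -> ComparisonResult:
    """Two-sample t test on cost-valid costs (Welch unless ``pooled``)."""
    a, b = _split_costs(records)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("each group needs >= 2 cost-valid records")
    stat, p = stats.ttest_ind(a, b, equal_var=pooled)
    return ComparisonResult("cost", "t_test", float(stat), float(p))


def compare_los(records: Sequence[PatientRecord], exact: bool = False) -> ComparisonResult:
    """Wilcoxon rank-sum on LOS, both groups, all records.

    Default is the tie-corrected normal approximation with continuity
    correction; ``exact=True`` uses the exact null distribution (no ties).
    """
    a = np.array([r.los for r in records if r.complication], dtype=float)
    b = np.array([r.los for r in records if not r.complication], dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return ComparisonResult("los", "wilcoxon_rank_sum", 0.0, 1.0)
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return ComparisonResult("los", "wilcoxon_rank_sum", float(res.statistic),
                            float(min(res.pvalue, 1.0)))


def compare_readmission(records: Sequence[PatientRecord],
                        continuity: bool = False) -> ComparisonResult:
    """Pearson chi-squared (df 1) on the group x readmitted 2x2 table.

    No continuity correction by default; the cells this model targets are
    large enough that it is immaterial.
    """
    table = readmission_table(records)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise InsufficientDataError("degenerate 2x2 table (zero margin)")
    if (table == table[0]).all():  # identical rows: statistic exactly 0
        return ComparisonResult("readmission", "chi_squared", 0.0, 1.0)
    chi2, p, _, _ = stats.chi2_contingency(table, correction=continuity)
    return ComparisonResult("readmission", "chi_squared", float(chi2), float(p))


def readmission_table(records: Sequence[PatientRecord]) -> np.ndarray:
    """2x2 counts: rows with/without complications, cols readmitted yes/no."""
    t = np.zeros((2, 2), dtype=np.int64)
    for r in records:
        i = 0 if r.complication else 1
        j = 0 if r.readmit_30d else 1
        t[i, j] += 1
    return t
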