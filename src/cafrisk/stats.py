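"""Baseline-table statistics: pooled two-sample t-tests and Pearson chi-square.

Continuous variables are compared with the pooled-variance (Student) t-test —
either from raw samples or directly from published (mean, SD, n) summaries —
and categorical variables with the uncorrected Pearson chi-square test.  Both
choices match how the reference KOA/CAF cohort tables were computed (the
printed statistics recompute under pooled t and uncorrected chi-square).

The module also ships the published summary statistics of that cohort
(training-vs-testing baseline and CAF-vs-no-CAF univariate comparison) so the
printed test statistics can be reproduced without any raw data.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import CohortTable

__all__ = [
    "GroupSummary",
    "ContingencyTable",
    "TestResult",
    "pooled_t_from_summary",
    "pooled_t_from_raw",
    "chi_square",
    "baseline_table",
    "TRAIN_TEST_SUMMARIES",
    "TRAIN_TEST_TABLES",
    "CAF_GROUP_SUMMARIES",
    "CAF_GROUP_TABLES",
]


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple | None = None
    col_labels: tuple | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")
        if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
            raise ValueError("all row and column marginals must be > 0")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_two_tailed: float
    method: str


def pooled_t_from_summary(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Student (pooled-variance) two-sample t-test from group summaries.

    sp^2 = ((na-1) sa^2 + (nb-1) sb^2) / (na+nb-2);
    t = (ma - mb) / (sp * sqrt(1/na + 1/nb)); df = na + nb - 2.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0.0:
        if a.mean == b.mean:
            return TestResult(statistic=0.0, df=float(df), p_two_tailed=1.0,
                              method="pooled_t")
        raise ValueError("zero pooled variance with unequal means (infinite statistic)")
    t, p = sps.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=True
    )
    return TestResult(statistic=float(t), df=float(df), p_two_tailed=float(p),
                      method="pooled_t")


def _summary(x: np.ndarray) -> GroupSummary:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.any(~np.isfinite(x)):
        raise ValueError("samples must be finite")
    return GroupSummary(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=int(x.size))


def pooled_t_from_raw(xa, xb) -> TestResult:
    """Pooled t-test from raw samples, via their computed summaries."""
    return pooled_t_from_summary(_summary(np.asarray(xa)), _summary(np.asarray(xb)))


def chi_square(table: ContingencyTable) -> TestResult:
    """Uncorrected Pearson chi-square test of independence."""
    res = sps.chi2_contingency(table.counts, correction=False)
    return TestResult(statistic=float(res.statistic), df=float(res.dof),
                      p_two_tailed=float(res.pvalue), method="pearson_chi2")


@dataclass(frozen=True)
class BaselineRow:
    variable: str
    kind: str
    summary: dict
    test: TestResult


def baseline_table(cohort: CohortTable, group_col: str | None = None) -> list[BaselineRow]:
    """Per-variable group comparison of a cohort (the classic 'Table 1').

    Continuous variables get a pooled t-test, binary/categorical variables a
    Pearson chi-square on the full cross-tabulation.  Rows follow the input
    column order.
    """
    group_col = group_col or cohort.outcome
    g = cohort.frame[group_col].to_numpy()
    levels = np.unique(g)
    if len(levels) != 2:
        raise ValueError(f"group column {group_col!r} must be binary")
    rows: list[BaselineRow] = []
    for name in cohort.frame.columns:
        if name == group_col:
            continue
        kind = cohort.kind_of(name)
        col = cohort.frame[name]
        if kind == "continuous":
            xa = col[g == levels[1]].to_numpy(dtype=float)
            xb = col[g == levels[0]].to_numpy(dtype=float)
            test = pooled_t_from_raw(xa, xb)
            summary = {
                str(levels[1]): (float(xa.mean()), float(xa.std(ddof=1)), int(xa.size)),
                str(levels[0]): (float(xb.mean()), float(xb.std(ddof=1)), int(xb.size)),
            }
        else:
            ct = pd.crosstab(g, col)
            table = ContingencyTable(
                counts=ct.to_numpy(),
                row_labels=tuple(ct.index),
                col_labels=tuple(ct.columns),
            )
            test = chi_square(table)
            summary = {str(r): {str(c): int(ct.loc[r, c]) for c in ct.columns} for r in ct.index}
        rows.append(BaselineRow(variable=name, kind=kind, summary=summary, test=test))
    return rows


# ---------------------------------------------------------------------------
# Published summary statistics of the reference KOA/CAF cohort
# ---------------------------------------------------------------------------
# (mean, sd, n) per group; these are the inputs from which the printed test
# statistics are recomputed.  Training n = 433, testing n = 108;
# CAF n = 360, no-CAF n = 181.

def _gs(mean, sd, n):
    return GroupSummary(mean=mean, sd=sd, n=n)


TRAIN_TEST_SUMMARIES: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "age": (_gs(64.52, 13.23, 433), _gs(65.12, 11.46, 108)),
    "bmi": (_gs(23.98, 3.15, 433), _gs(24.12, 3.42, 108)),
    "duration": (_gs(15.82, 4.62, 433), _gs(16.11, 4.54, 108)),
    "knee_extensor_moment": (_gs(1.21, 0.38, 433), _gs(1.19, 0.36, 108)),
    "tug_time": (_gs(12.45, 3.67, 433), _gs(12.88, 3.45, 108)),
    "gait_speed": (_gs(0.92, 0.21, 433), _gs(0.90, 0.22, 108)),
    "womac_pain": (_gs(5.49, 2.24, 433), _gs(5.53, 2.17, 108)),
    "womac_stiffness": (_gs(2.15, 0.49, 433), _gs(2.17, 0.43, 108)),
    "womac_function": (_gs(22.53, 9.25, 433), _gs(23.18, 10.23, 108)),
    "hads_anxiety": (_gs(10.21, 3.52, 433), _gs(10.35, 3.47, 108)),
}

# train x category counts (rows: training, testing)
TRAIN_TEST_TABLES: dict[str, ContingencyTable] = {
    "sex": ContingencyTable(np.array([[130, 303], [34, 74]])),
    "education": ContingencyTable(np.array([[155, 234, 44], [38, 59, 11]])),
    "living_mode": ContingencyTable(np.array([[41, 232, 61, 99], [10, 58, 16, 24]])),
    "kl_grade": ContingencyTable(np.array([[266, 167], [63, 45]])),
    "mri_bone_marrow_edema": ContingencyTable(np.array([[189, 244], [45, 63]])),
    "mri_joint_effusion": ContingencyTable(np.array([[156, 277], [42, 66]])),
}

CAF_GROUP_SUMMARIES: dict[str, tuple[GroupSummary, GroupSummary]] = {
    "age": (_gs(67.35, 14.23, 360), _gs(61.85, 13.77, 181)),
    "bmi": (_gs(24.97, 3.78, 360), _gs(23.12, 3.15, 181)),
    "knee_extensor_moment": (_gs(1.05, 0.32, 360), _gs(1.45, 0.41, 181)),
    "tug_time": (_gs(14.52, 3.85, 360), _gs(10.11, 2.46, 181)),
    "womac_pain": (_gs(6.45, 2.01, 360), _gs(4.73, 1.24, 181)),
    "hads_anxiety": (_gs(10.83, 3.31, 360), _gs(9.11, 2.59, 181)),
}

# CAF group x category counts (rows: CAF, no-CAF)
CAF_GROUP_TABLES: dict[str, ContingencyTable] = {
    "sex": ContingencyTable(np.array([[78, 282], [86, 95]])),
    "kl_grade": ContingencyTable(np.array([[202, 158], [130, 51]])),
}
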