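"""Cohort-level statistics: grading, grouping, regressions, box summaries.

Implements the method-comparison layer: CRN steatosis grading from the
pathologist's percentage, the mild/severe fibrosis split (F0–F2 vs F3–F4,
i.e. no bridging fibrosis vs bridging/cirrhosis), ordinary least-squares
regression with Pearson correlation for comparing fat-fraction methods,
box-plot summaries with 1.5·IQR (mild) and 3·IQR (extreme) outlier fences,
a nonparametric two-group difference test, per-grade group summary tables,
and the k-sweep table of TMFF_MR-vs-TMFF_DIA regression slopes.

Quartiles use linear interpolation of order statistics (the numpy default),
so the outlier fences are exactly reproducible.  No multiple-testing
correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .water_model import DEFAULT_K_SWEEP

__all__ = ["RegressionResult", "BoxSummary", "assign_steatosis_grade",
           "split_fibrosis_groups", "linear_regression", "box_summary",
           "group_difference_test", "grade_group_summary",
           "k_sweep_comparison"]

MILD_FIBROSIS_STAGES = (0, 1, 2)
SEVERE_FIBROSIS_STAGES = (3, 4)


@dataclass(frozen=True)
class RegressionResult:
    """OLS slope/intercept with the Pearson correlation of the two methods."""

    slope: float
    intercept: float
    pearson_r: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|pearson_r| must be <= 1")
        if self.n < 3:
            raise ValueError("n must be >= 3")


@dataclass(frozen=True)
class BoxSummary:
    """Quartiles plus mild (1.5·IQR) and extreme (3·IQR) outliers."""

    q1: float
    q2: float
    q3: float
    iqr: float
    mild_outliers: tuple[float, ...]
    extreme_outliers: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.q1 <= self.q2 <= self.q3:
            raise ValueError("quartiles must be ordered")


def assign_steatosis_grade(va_percent: float) -> int:
    """CRN steatosis grade from the percent of fat-containing hepatocytes.

    Bands: < 5% → S0; 5–33% → S1; > 33–66% → S2; > 66% → S3 (boundary
    values 5 and 33 fall in S1, 66 in S2).
    """
    if not 0.0 <= va_percent <= 100.0:
        raise ValueError("va_percent must be in [0, 100]")
    if va_percent < 5.0:
        return 0
    if va_percent <= 33.0:
        return 1
    if va_percent <= 66.0:
        return 2
    return 3


def split_fibrosis_groups(cohort: pd.DataFrame,
                          stage_column: str = "fibrosis_stage",
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into mild-to-no (F0–F2) and severe (F3–F4) fibrosis groups."""
    stages = cohort[stage_column]
    known = set(MILD_FIBROSIS_STAGES) | set(SEVERE_FIBROSIS_STAGES)
    bad = set(stages.unique()) - known
    if bad:
        raise ValueError(f"unknown fibrosis stage value(s): {sorted(bad)}")
    mild = cohort[stages.isin(MILD_FIBROSIS_STAGES)]
    severe = cohort[stages.isin(SEVERE_FIBROSIS_STAGES)]
    return mild, severe


def linear_regression(x, y) -> RegressionResult:
    """OLS of y on x with the Pearson correlation, for method comparison."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = sps.linregress(x, y)
    return RegressionResult(slope=float(res.slope),
                            intercept=float(res.intercept),
                            pearson_r=float(res.rvalue), n=int(x.size))


def box_summary(values) -> BoxSummary:
    """Quartiles (linear-interpolation convention) and fence-based outliers.

    Mild outliers lie beyond q1 − 1.5·IQR or q3 + 1.5·IQR but inside the
    3·IQR fences; extreme outliers lie beyond q1 − 3·IQR or q3 + 3·IQR.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("need >= 4 values for a box summary")
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_mild, hi_mild = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    lo_ext, hi_ext = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    extreme = v[(v < lo_ext) | (v > hi_ext)]
    mild = v[((v < lo_mild) | (v > hi_mild)) & (v >= lo_ext) & (v <= hi_ext)]
    return BoxSummary(q1=float(q1), q2=float(q2), q3=float(q3),
                      iqr=float(iqr),
                      mild_outliers=tuple(float(x) for x in np.sort(mild)),
                      extreme_outliers=tuple(float(x) for x in
                                             np.sort(extreme)))


def group_difference_test(a, b, method: str = "mannwhitney") -> float:
    """Two-sided two-group difference p-value.

    Default is the Mann–Whitney U test (exact for small tie-free samples,
    normal approximation with tie correction otherwise); ``method="welch"``
    selects Welch's unequal-variance t test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("both groups need >= 3 observations")
    if method == "mannwhitney":
        return float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                      method="auto").pvalue)
    if method == "welch":
        return float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    raise ValueError(f"unknown method {method!r}")


def grade_group_summary(cohort: pd.DataFrame, value_column: str,
                        group_column: str = "fibrosis_group",
                        grade_column: str = "steatosis_grade",
                        ) -> pd.DataFrame:
    """Mean ± SD, n and box statistics per steatosis grade × group.

    Adds the percentage difference between the two group means per grade
    (relative to the larger mean).  Cells with no patients are reported as
    missing rather than raising.
    """
    if group_column not in cohort or grade_column not in cohort:
        raise ValueError("grouping columns missing from cohort table")
    rows = []
    grades = sorted(cohort[grade_column].unique())
    groups = sorted(cohort[group_column].unique())
    for grade in grades:
        sub = cohort[cohort[grade_column] == grade]
        means = {}
        for grp in groups:
            vals = sub.loc[sub[group_column] == grp, value_column].to_numpy()
            row = {"steatosis_grade": grade, "group": grp, "n": vals.size,
                   "mean": np.nan, "sd": np.nan,
                   "q1": np.nan, "median": np.nan, "q3": np.nan,
                   "n_mild_outliers": 0, "n_extreme_outliers": 0}
            if vals.size:
                row["mean"] = float(vals.mean())
                row["sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
                means[grp] = row["mean"]
            if vals.size >= 4:
                bs = box_summary(vals)
                row.update(q1=bs.q1, median=bs.q2, q3=bs.q3,
                           n_mild_outliers=len(bs.mild_outliers),
                           n_extreme_outliers=len(bs.extreme_outliers))
            rows.append(row)
        pct = np.nan
        if len(means) == 2:
            m = list(means.values())
            ref = max(abs(m[0]), abs(m[1]))
            pct = 100.0 * abs(m[0] - m[1]) / ref if ref > 0 else 0.0
        for row in rows[-len(groups):]:
            row["pct_difference_between_groups"] = pct
    return pd.DataFrame(rows)


def k_sweep_comparison(cohort: pd.DataFrame,
                       k_values=DEFAULT_K_SWEEP,
                       dia_column: str = "tmff_dia",
                       mr_column_fmt: str = "tmff_mr_k_{k:g}",
                       ) -> pd.DataFrame:
    """Slope and Pearson r of TMFF_MR vs TMFF_DIA per fibrosis group per k.

    Expects one TMFF_MR column per k (``mr_column_fmt`` names them).  A
    group with fewer than three patients is skipped with a warning and the
    table is emitted for the remaining group only.
    """
    mild, severe = split_fibrosis_groups(cohort)
    rows = []
    for label, grp in (("F0-F2", mild), ("F3-F4", severe)):
        if len(grp) < 3:
            warnings.warn(f"group {label} has {len(grp)} patients; "
                          "skipped in k-sweep table", stacklevel=2)
            continue
        for k in k_values:
            col = mr_column_fmt.format(k=k)
            reg = linear_regression(grp[dia_column], grp[col])
            rows.append({"k": float(k), "group": label, "slope": reg.slope,
                         "pearson_r": reg.pearson_r, "n": reg.n})
    return pd.DataFrame(rows)
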