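"""Test–retest reliability: single-measure absolute-agreement ICC.

ICC(A,1) from the two-way ANOVA decomposition of an animals x days table
(rows = subjects, columns = sessions):

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with MSR/MSC/MSE the row, column and residual mean squares. The 95%
confidence interval follows the McGraw–Wong absolute-agreement
construction, and estimates are mapped to the conventional reliability
categories: poor (< 0.5), moderate (0.5–0.75), good (0.75–0.90),
excellent (>= 0.90). Category joins use upper-open intervals, so 0.90 is
excellent and 0.75 is good (configurable notation ambiguity; see docs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .errors import DataIntegrityError, DegenerateDataError, ParameterError

CATEGORY_EDGES = ((0.5, "poor"), (0.75, "moderate"), (0.90, "good"))


@dataclass
class ICCResult:
    icc: float
    f_value: float
    ci95: tuple[float, float]
    df: tuple[float, float]
    category: str
    n_subjects: int
    k_sessions: int


def classify_icc(value: float) -> str:
    """Reliability category of an ICC estimate (negatives are 'poor')."""
    if not math.isfinite(value):
        raise ParameterError("ICC value must be finite")
    if value > 1:
        raise ParameterError("ICC cannot exceed 1")
    for edge, name in CATEGORY_EDGES:
        if value < edge:
            return name
    return "excellent"


def icc_a1(values: np.ndarray | pd.DataFrame, alpha: float = 0.05
           ) -> ICCResult:
    """ICC(A,1): two-way model, absolute agreement, single measurement.

    ``values`` is a complete n_subjects x k_sessions matrix of one metric.
    Returns the estimate, the F statistic MSR/MSE with df (n-1, (n-1)(k-1)),
    and the (1 - alpha) absolute-agreement confidence interval.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2:
        raise ParameterError("ratings must be a 2-D matrix")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ParameterError("need at least 2 subjects and 2 sessions")
    if np.any(~np.isfinite(m)):
        raise ParameterError("ratings matrix must be complete and finite "
                             "(no imputation is performed)")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    if ss_total == 0:
        raise DegenerateDataError("constant ratings matrix: ICC undefined")

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:
        raise DegenerateDataError("zero ICC denominator")
    icc = (msr - mse) / denom
    f_value = msr / mse if mse > 0 else float("inf")
    df = (n - 1.0, (n - 1.0) * (k - 1.0))

    # McGraw & Wong absolute-agreement CI
    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else float("inf")
    b = 1.0 + (k * icc * (n - 1.0)) / (n * (1.0 - icc)) if icc < 1 \
        else float("inf")
    if math.isfinite(a) and (a * msc + b * mse) > 0:
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1.0)
            + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        )
        f_l = f_dist.ppf(1.0 - alpha / 2.0, n - 1.0, v)
        f_u = f_dist.ppf(1.0 - alpha / 2.0, v, n - 1.0)
        lower = (n * (msr - f_l * mse)
                 / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
        upper = (n * (f_u * msr - mse)
                 / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
    else:  # perfect agreement: interval collapses
        lower = upper = 1.0
    return ICCResult(icc=float(icc), f_value=float(f_value),
                     ci95=(float(lower), float(upper)), df=df,
                     category=classify_icc(float(icc)),
                     n_subjects=n, k_sessions=k)


def icc_table(metrics: pd.DataFrame, metric: str,
              subject_col: str = "animal_id", session_col: str = "day",
              group_col: str = "sex", strict: bool = True,
              log10: bool = False) -> pd.DataFrame:
    """Per-group ICC(A,1) rows for one metric column of a long table.

    Each subject must have a complete session series; incomplete subjects
    raise (strict=True) or are dropped with a warning column otherwise.
    Output columns mirror the conventional reliability-table layout:
    metric, group, F, df1, df2, ICC, CI_low, CI_high, category.
    """
    if metric not in metrics.columns:
        raise ParameterError(f"metric column {metric!r} missing")
    rows = []
    for group, sub in metrics.groupby(group_col, sort=True):
        wide = sub.pivot_table(index=subject_col, columns=session_col,
                               values=metric, aggfunc="mean")
        incomplete = wide.index[wide.isna().any(axis=1)].tolist()
        if incomplete:
            if strict:
                missing = {
                    subj: wide.columns[wide.loc[subj].isna()].tolist()
                    for subj in incomplete
                }
                raise DataIntegrityError(
                    f"incomplete series for group {group!r}: {missing}"
                )
            wide = wide.drop(index=incomplete)
        vals = wide.to_numpy()
        if log10:
            if np.any(vals <= 0):
                raise ParameterError("log10 requires strictly positive values")
            vals = np.log10(vals)
        res = icc_a1(vals)
        rows.append({
            "metric": metric, "group": group, "F": res.f_value,
            "df1": res.df[0], "df2": res.df[1], "ICC": res.icc,
            "CI_low": res.ci95[0], "CI_high": res.ci95[1],
            "category": res.category, "n_subjects": res.n_subjects,
            "k_sessions": res.k_sessions,
            "n_dropped": len(incomplete) if not strict else 0,
        })
    return pd.DataFrame(rows)
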