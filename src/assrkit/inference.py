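"""Normality-routed group comparisons and within-animal drug deltas.

The decision tree mirrors standard pharmaco-EEG practice: Shapiro–Wilk
normality at alpha_norm routes each comparison to the parametric test
(paired or unpaired t) or its rank-based counterpart (Wilcoxon
matched-pairs, Mann–Whitney U). For paired designs normality is assessed
on the within-subject differences. All tests are two-sided; p-values are
reported raw (no multiple-testing correction by default, a Holm option is
available for sensitivity analyses).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ParameterError


@dataclass
class ComparisonResult:
    test_name: str            # paired t | Wilcoxon matched-pairs |
    #                           unpaired t | Mann-Whitney U
    statistic: float
    p_value: float
    n: tuple[int, int]
    effect_direction: str     # "a>b" | "a<b" | "a=b"
    normality_p: tuple[float, ...]
    parametric: bool


def _direction(a: np.ndarray, b: np.ndarray) -> str:
    d = float(np.mean(a) - np.mean(b))
    if d > 0:
        return "a>b"
    if d < 0:
        return "a<b"
    return "a=b"


def route_test(a, b, paired: bool, alpha_norm: float = 0.05,
               force: str | None = None) -> ComparisonResult:
    """Two-sided comparison of samples a and b with normality routing.

    paired=True assumes a and b are aligned per subject; routing then uses
    Shapiro–Wilk on the differences. ``force`` ("parametric" /
    "nonparametric") bypasses routing for sensitivity checks.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1:
        raise ParameterError("samples must be 1-D")
    if min(a.size, b.size) < 3:
        raise ParameterError("need n >= 3 per sample (Shapiro-Wilk minimum)")
    if paired and a.size != b.size:
        raise ParameterError("paired samples must have equal length")

    if paired:
        diffs = a - b
        if np.ptp(diffs) == 0:
            raise DegenerateDataError(
                "all paired differences identical; the paired tests are "
                "undefined (zero variance)"
            )
        norm_p = (float(stats.shapiro(diffs).pvalue),)
    else:
        norm_p = (float(stats.shapiro(a).pvalue),
                  float(stats.shapiro(b).pvalue))

    if force is None:
        parametric = all(p > alpha_norm for p in norm_p)
    elif force in ("parametric", "nonparametric"):
        parametric = force == "parametric"
    else:
        raise ParameterError("force must be 'parametric' or 'nonparametric'")

    if paired:
        if parametric:
            res = stats.ttest_rel(a, b)
            name = "paired t"
        else:
            # Wilcoxon's original rule: zero differences dropped; exact
            # distribution for n <= 25 when there are no ties.
            nz = diffs[diffs != 0]
            method = "exact" if (nz.size <= 25
                                 and np.unique(np.abs(nz)).size == nz.size) \
                else "approx"
            res = stats.wilcoxon(a, b, zero_method="wilcox", method=method)
            name = "Wilcoxon matched-pairs"
    else:
        if parametric:
            res = stats.ttest_ind(a, b)
            name = "unpaired t"
        else:
            pooled = np.concatenate([a, b])
            exact = (a.size + b.size <= 20
                     and np.unique(pooled).size == pooled.size)
            res = stats.mannwhitneyu(
                a, b, alternative="two-sided",
                method="exact" if exact else "asymptotic")
            name = "Mann-Whitney U"

    return ComparisonResult(
        test_name=name, statistic=float(res.statistic),
        p_value=float(res.pvalue), n=(a.size, b.size),
        effect_direction=_direction(a, b), normality_p=norm_p,
        parametric=parametric,
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional sensitivity analysis)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def delta_effect(metric_by_condition: pd.DataFrame,
                 conditions: tuple[str, str] = ("KET", "SAL"),
                 subject_col: str = "animal_id",
                 condition_col: str = "condition",
                 value_col: str = "value") -> pd.DataFrame:
    """Per-animal drug-effect delta, value_KET - value_SAL.

    Negative deltas mean a reduction under the first condition (ketamine).
    Every animal must contribute both conditions; carries through any
    columns constant within animal (e.g. sex).
    """
    test_cond, ref_cond = conditions
    wide = metric_by_condition.pivot_table(
        index=subject_col, columns=condition_col, values=value_col,
        aggfunc="mean")
    for cond in conditions:
        if cond not in wide.columns:
            missing = list(wide.index)
            raise ParameterError(
                f"condition {cond!r} absent for animals {missing}"
            )
    bad = wide.index[wide[list(conditions)].isna().any(axis=1)].tolist()
    if bad:
        raise ParameterError(
            f"animals missing a condition value: {bad}"
        )
    out = pd.DataFrame({
        subject_col: wide.index,
        "delta": (wide[test_cond] - wide[ref_cond]).to_numpy(),
    })
    carry = [c for c in metric_by_condition.columns
             if c not in (subject_col, condition_col, value_col)]
    for c in carry:
        per_subject = metric_by_condition.groupby(subject_col)[c].agg(
            lambda s: s.iloc[0] if s.nunique() == 1 else np.nan)
        out[c] = per_subject.reindex(wide.index).to_numpy()
    return out.reset_index(drop=True)


def compare_sexes(metrics: pd.DataFrame, value_col: str = "value",
                  subject_col: str = "animal_id", sex_col: str = "sex",
                  alpha_norm: float = 0.05) -> ComparisonResult:
    """Unpaired male-vs-female comparison of per-animal means.

    Repeated sessions (e.g. the consecutive baseline days) are first
    averaged within animal, matching the pooled presentation of multi-day
    group comparisons; requires >= 3 animals per sex.
    """
    per_animal = metrics.groupby([subject_col, sex_col])[value_col] \
        .mean().reset_index()
    males = per_animal.loc[per_animal[sex_col] == "M", value_col].to_numpy()
    females = per_animal.loc[per_animal[sex_col] == "F", value_col].to_numpy()
    if min(males.size, females.size) < 3:
        raise ParameterError("need at least 3 animals per sex")
    return route_test(males, females, paired=False, alpha_norm=alpha_norm)
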