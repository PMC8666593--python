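"""Cohort-level comparisons of adipose and biomechanical metrics.

The analysis battery mirrors an exploratory clinical comparison: one-way
ANOVA of each metric across a binary grouping (pressure-injury history,
presence of spasms), Pearson correlations with continuous covariates, a
rule that removes fully fat-infiltrated subjects (negative IMAT effect
size) before re-testing, and participant-characteristics summaries.

For two groups the ANOVA is algebraically identical to the pooled two-sided
t test (F = t^2); :func:`group_compare` verifies that identity on every
call.  No multiple-testing adjustment is applied — p values are raw, as in
an exploratory analysis — and missing values are dropped pairwise per
analysis, so each result carries its own n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import ParameterError, UndefinedStatisticError

logger = logging.getLogger(__name__)

#: columns of a metrics-plus-covariates cohort table
COHORT_COLUMNS = [
    "subject_id", "pri_history", "ischial_pri", "spasms", "bmi",
    "years_wheelchair", "hip_breadth_in", "subqf_effect_size",
    "imat_effect_size", "bulk_thickness_mm", "sagittal_radius_mm",
]


@dataclass
class GroupComparison:
    """Two-group one-way ANOVA with a pooled-variance CI of the difference."""

    metric: str
    group: str
    levels: tuple
    means: tuple[float, float]
    sds: tuple[float, float]
    ns: tuple[int, int]
    difference: float  # mean(level0) - mean(level1)
    ci95: tuple[float, float]
    f_statistic: float
    p_value: float

    def to_row(self) -> dict:
        return {
            "analysis": "group_compare",
            "metric": self.metric,
            "group": self.group,
            "n": sum(self.ns),
            "estimate": self.difference,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "statistic": self.f_statistic,
            "p_value": self.p_value,
        }


def group_compare(
    table: pd.DataFrame, metric: str, group: str
) -> GroupComparison:
    """One-way ANOVA of ``metric`` across the two levels of ``group``.

    Rows missing either column are dropped.  The reported difference is
    mean(first level) - mean(second level) with levels in sorted order, and
    its 95% CI uses the pooled-variance t interval.
    """
    sub = table[[metric, group]].dropna()
    levels = sorted(sub[group].unique())
    if len(levels) != 2:
        raise ParameterError(
            f"'{group}' must have exactly 2 non-missing levels, got {levels}"
        )
    a = sub.loc[sub[group] == levels[0], metric].to_numpy(dtype=float)
    b = sub.loc[sub[group] == levels[1], metric].to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("each group needs at least 2 non-missing values")

    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate within-group variance: define the test by its limit
        if a.mean() == b.mean():
            f_stat, p_anova = 0.0, 1.0
        else:
            f_stat, p_anova = float("inf"), 0.0
    else:
        f_stat, p_anova = sps.f_oneway(a, b)
        t_stat, _ = sps.ttest_ind(a, b, equal_var=True)
        # two-group ANOVA and the pooled t test are the same test (F = t^2)
        assert math.isclose(f_stat, t_stat**2, rel_tol=1e-9, abs_tol=1e-12)

    na, nb = a.size, b.size
    diff = float(a.mean() - b.mean())
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (
        na + nb - 2
    )
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    tcrit = sps.t.ppf(0.975, na + nb - 2)
    return GroupComparison(
        metric=metric,
        group=group,
        levels=tuple(levels),
        means=(float(a.mean()), float(b.mean())),
        sds=(float(np.std(a, ddof=1)), float(np.std(b, ddof=1))),
        ns=(na, nb),
        difference=diff,
        ci95=(diff - tcrit * se, diff + tcrit * se),
        f_statistic=float(f_stat),
        p_value=float(p_anova),
    )


def correlate(table: pd.DataFrame, x: str, y: str) -> tuple[float, float]:
    """Pearson r and two-sided p over pairwise-complete rows."""
    sub = table[[x, y]].dropna()
    if len(sub) < 3:
        raise ParameterError(
            f"correlation of '{x}' and '{y}' needs >= 3 complete pairs"
        )
    xv = sub[x].to_numpy(dtype=float)
    yv = sub[y].to_numpy(dtype=float)
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise UndefinedStatisticError(
            f"zero variance in '{x if np.std(xv) == 0 else y}'"
        )
    r, p = sps.pearsonr(xv, yv)
    return float(r), float(p)


def exclude_full_infiltration(table: pd.DataFrame) -> pd.DataFrame:
    """Drop fully fat-infiltrated subjects (IMAT effect size < 0).

    A negative IMAT effect size means the gluteus is brighter than the
    reference adipose — muscle indistinguishable from fat.  The boundary
    value 0 is kept.
    """
    if "imat_effect_size" not in table.columns:
        raise ParameterError("table has no 'imat_effect_size' column")
    kept = table[table["imat_effect_size"] >= 0]
    removed = len(table) - len(kept)
    logger.info("excluded %d fully fat-infiltrated subjects", removed)
    if kept.empty:
        logger.warning("exclusion removed every subject")
    return kept


def cohort_summary(
    table: pd.DataFrame,
    group: str = "pri_history",
    continuous: list[str] | None = None,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Participant-characteristics summary, per group and overall.

    Continuous variables get n, mean, SD, median, min, max; categorical
    variables get counts and percentages.  The overall mean of a continuous
    variable equals the sample-size-weighted average of the group means by
    construction (the same rows are pooled).
    """
    if table.empty:
        raise ParameterError("cohort table is empty")
    if continuous is None:
        continuous = [
            c
            for c in (
                "bmi", "years_wheelchair", "hip_breadth_in",
                "subqf_effect_size", "imat_effect_size",
                "bulk_thickness_mm", "sagittal_radius_mm",
            )
            if c in table.columns
        ]
    if categorical is None:
        categorical = [c for c in ("spasms", "ischial_pri") if c in table.columns]

    def _blocks():
        yield "all", table
        if group in table.columns:
            for level, block in table.groupby(group):
                yield f"{group}={level}", block

    rows = []
    for label, block in _blocks():
        for var in continuous:
            vals = block[var].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                continue
            rows.append(
                {
                    "group": label, "variable": var, "n": vals.size,
                    "mean": float(vals.mean()),
                    "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                    "median": float(np.median(vals)),
                    "min": float(vals.min()), "max": float(vals.max()),
                }
            )
        for var in categorical:
            vals = block[var].dropna()
            if vals.empty:
                continue
            n = len(vals)
            for level, count in vals.value_counts().sort_index().items():
                rows.append(
                    {
                        "group": label, "variable": f"{var}={level}",
                        "n": n, "count": int(count),
                        "percent": 100.0 * count / n,
                    }
                )
    return pd.DataFrame(rows)


def standard_battery(table: pd.DataFrame) -> pd.DataFrame:
    """The full exploratory analysis over one cohort table.

    Group comparisons of every imaging metric by pressure-injury history,
    the spasms comparison of IMAT, correlations of both effect sizes with
    the continuous covariates and biomechanical measures, each other, and
    the PrI-history comparisons repeated with fully infiltrated subjects
    excluded.
    """
    rows: list[dict] = []
    metrics = [
        m
        for m in (
            "subqf_effect_size", "imat_effect_size",
            "bulk_thickness_mm", "sagittal_radius_mm",
        )
        if m in table.columns
    ]

    def _try(fn, row_extra):
        try:
            return fn()
        except (ParameterError, UndefinedStatisticError) as exc:
            rows.append({**row_extra, "error": str(exc)})
            return None

    if "pri_history" in table.columns:
        for m in metrics:
            res = _try(
                lambda m=m: group_compare(table, m, "pri_history"),
                {"analysis": "group_compare", "metric": m,
                 "group": "pri_history"},
            )
            if res:
                rows.append(res.to_row())
    if "spasms" in table.columns and "imat_effect_size" in table.columns:
        res = _try(
            lambda: group_compare(table, "imat_effect_size", "spasms"),
            {"analysis": "group_compare", "metric": "imat_effect_size",
             "group": "spasms"},
        )
        if res:
            rows.append(res.to_row())

    cont = [
        c
        for c in ("bmi", "years_wheelchair", "hip_breadth_in",
                  "bulk_thickness_mm", "sagittal_radius_mm")
        if c in table.columns
    ]
    pairs = [("subqf_effect_size", c) for c in cont]
    pairs += [("imat_effect_size", c) for c in cont
              if c not in ("subqf_effect_size",)]
    if {"subqf_effect_size", "imat_effect_size"} <= set(table.columns):
        pairs.append(("subqf_effect_size", "imat_effect_size"))
    for x, y in pairs:
        if x not in table.columns or y not in table.columns or x == y:
            continue
        out = _try(
            lambda x=x, y=y: correlate(table, x, y),
            {"analysis": "correlation", "metric": y, "group": x},
        )
        if out:
            r, p = out
            n = len(table[[x, y]].dropna())
            rows.append(
                {"analysis": "correlation", "metric": y, "group": x,
                 "n": n, "estimate": r, "p_value": p}
            )

    if {"imat_effect_size", "pri_history"} <= set(table.columns):
        lean = exclude_full_infiltration(table)
        for m in metrics:
            res = _try(
                lambda m=m, lean=lean: group_compare(lean, m, "pri_history"),
                {"analysis": "group_compare_excl_full_infiltration",
                 "metric": m, "group": "pri_history"},
            )
            if res:
                row = res.to_row()
                row["analysis"] = "group_compare_excl_full_infiltration"
                rows.append(row)
    return pd.DataFrame(rows)
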