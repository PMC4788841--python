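"""Prevalences, chi-square tests, and disparity measures across quintiles.

The central analysis: a Pearson chi-square over the 5 (deprivation
quintile) × 4 (BMI category) table — 12 degrees of freedom — plus a 1-df
most-vs-least-deprived 2x2 test, per-quintile obesity prevalences, and
absolute (simple difference, percentage points) and relative (rate ratio)
disparity measures against the least-deprived quintile as reference.
Stratified analyses repeat the quintile comparison within age groups or
urban/rural strata. No continuity correction and no multiple-testing
adjustment are applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from emrlink.config import BMI_CATEGORIES

QUINTILES = (1, 2, 3, 4, 5)


def prevalence(numerator: int, denominator: int) -> float:
    """Percentage to one decimal: 100 * numerator / denominator."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator > denominator:
        raise ValueError("numerator cannot exceed denominator")
    return round(100.0 * numerator / denominator, 1)


def pearson_chi_square(table: np.ndarray | pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square with expected counts from the margins.

    Returns (statistic, degrees of freedom, upper-tail p-value). No
    continuity correction. A zero row or column margin is an error since
    expected counts must be positive.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValueError("table must be a 2-D array of non-negative counts")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero margin: expected cell counts must be positive")
    res = stats.chi2_contingency(obs, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


@dataclass
class DisparityTable:
    """Per-quintile prevalence with differences and ratios vs quintile 1."""

    prevalences: tuple[float, ...]
    simple_differences: tuple[float, ...]  # percentage points, 1 decimal
    rate_ratios: tuple[float, ...]  # 2 decimals

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quintile": QUINTILES,
                "prevalence_pct": self.prevalences,
                "simple_difference_pp": self.simple_differences,
                "rate_ratio": self.rate_ratios,
            }
        )


def disparity_measures(prevalences: tuple[float, ...] | list[float]) -> DisparityTable:
    """Absolute and relative disparity vs the least-deprived quintile.

    ``prevalences`` are the five per-quintile obesity prevalences in
    percent, quintile 1 (the reference) first. Simple difference is
    p_i − p_1 in percentage points (one decimal); the disparity rate
    ratio is p_i / p_1 (two decimals).
    """
    p = [float(v) for v in prevalences]
    if len(p) != 5:
        raise ValueError("expected 5 per-quintile prevalences")
    ref = p[0]
    if ref <= 0:
        raise ValueError("reference prevalence must be positive")
    diffs = tuple(round(v - ref, 1) for v in p)
    ratios = tuple(round(v / ref, 2) for v in p)
    return DisparityTable(tuple(p), diffs, ratios)


def quintile_category_table(assignments: pd.DataFrame, index: str = "combined") -> pd.DataFrame:
    """5x4 contingency table: deprivation quintile × BMI category."""
    col = f"{index}_q"
    table = pd.crosstab(assignments[col], assignments["bmi_category"])
    table = table.reindex(index=list(QUINTILES), columns=list(BMI_CATEGORIES), fill_value=0)
    return table


def quintile_prevalences(assignments: pd.DataFrame, index: str = "combined") -> pd.DataFrame:
    """Obesity prevalence per quintile: obese count, total, percent."""
    col = f"{index}_q"
    rows = []
    for q in QUINTILES:
        sub = assignments[assignments[col] == q]
        obese = int((sub["bmi_category"] == "obese").sum())
        total = len(sub)
        rows.append(
            {
                "quintile": q,
                "obese": obese,
                "total": total,
                "prevalence_pct": prevalence(obese, total) if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def extreme_quintile_test(
    q1: tuple[int, int], q5: tuple[int, int]
) -> tuple[float, int, float, float, float]:
    """Most- vs least-deprived 2x2 test.

    ``q1`` and ``q5`` are (obese count, total). Returns (chi-square, df=1,
    p-value, relative difference in percent, absolute difference in
    percentage points), with quintile 1 as reference.
    """
    (o1, n1), (o5, n5) = q1, q5
    if n1 <= 0 or n5 <= 0:
        raise ValueError("totals must be positive")
    table = np.array([[o1, n1 - o1], [o5, n5 - o5]], dtype=float)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        statistic, df, p = 0.0, 1, 1.0
    else:
        statistic, df, p = pearson_chi_square(table)
    p1 = 100.0 * o1 / n1
    p5 = 100.0 * o5 / n5
    relative = 100.0 * (p5 / p1 - 1.0) if p1 > 0 else float("inf")
    absolute = p5 - p1
    return statistic, df, p, relative, absolute


def stratified_analysis(
    assignments: pd.DataFrame,
    strata: str = "age_group",
    index: str = "combined",
    small_cell_threshold: int = 5,
) -> pd.DataFrame:
    """Obese counts by quintile within each stratum, with a chi-square test.

    ``strata`` is a column of ``assignments`` (``age_group`` or ``urban``).
    Percentages are each cell over the stratum's obese total, matching the
    stratified study tables. The chi-square tests obese/non-obese × quintile
    within the stratum; strata where any expected count falls below
    ``small_cell_threshold``, or with a single occupied quintile, are
    flagged as low-power (test still reported when computable).
    """
    col = f"{index}_q"
    rows = []
    for stratum, sub in assignments.groupby(strata, observed=True, sort=True):
        if sub.empty:
            continue
        obese = sub[sub["bmi_category"] == "obese"]
        n_obese = len(obese)
        per_q = {
            q: int((obese[col] == q).sum()) for q in QUINTILES
        }
        occupied = [q for q in QUINTILES if (sub[col] == q).any()]
        flagged = False
        statistic = df = p = float("nan")
        if len(occupied) >= 2 and 0 < n_obese < len(sub):
            table = np.array(
                [
                    [int(((sub[col] == q) & (sub["bmi_category"] == "obese")).sum()) for q in occupied],
                    [
                        int(((sub[col] == q) & (sub["bmi_category"] != "obese")).sum())
                        for q in occupied
                    ],
                ],
                dtype=float,
            )
            statistic, df, p = pearson_chi_square(table)
            expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
            flagged = bool((expected < small_cell_threshold).any())
        else:
            flagged = True
        row = {
            "stratum": stratum,
            "n": len(sub),
            "n_obese": n_obese,
            "chi_square": statistic,
            "df": df,
            "p_value": p,
            "low_power": flagged,
        }
        for q in QUINTILES:
            row[f"q{q}_obese"] = per_q[q]
            row[f"q{q}_pct_of_obese"] = (
                prevalence(per_q[q], n_obese) if n_obese else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
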