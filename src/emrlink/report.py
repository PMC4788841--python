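"""Assembled study outputs: distribution, stratified, and disparity tables.

``build_report`` collects the sample-distribution table (counts by sex,
age decade, deprivation quintile, BMI category), the attrition narrative,
the stratified analyses, the disparity tables, and per-area obesity
aggregates for external mapping. Cross-table consistency (category counts
summing to the sample size, stratified obese counts summing to the overall
obese count) is asserted on every build and fails loudly when violated.

Per-area aggregates reuse the de-identification threshold k: an area with
fewer than k patients is suppressed, keeping the privacy contract end to
end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from emrlink.cleaning import AttritionReport
from emrlink.config import AGE_BINS, BMI_CATEGORIES
from emrlink.disparity import (
    DisparityTable,
    QUINTILES,
    disparity_measures,
    quintile_prevalences,
    stratified_analysis,
)


def check_stratified_consistency(
    stratified: pd.DataFrame, total_obese: int
) -> None:
    """Obese cells across strata must sum to the overall obese count."""
    cell_cols = [f"q{q}_obese" for q in QUINTILES]
    total = int(stratified[cell_cols].to_numpy().sum())
    if total != total_obese:
        raise ValueError(
            f"stratified obese cells sum to {total}, expected {total_obese}"
        )


@dataclass
class StudyReport:
    """All human-readable study outputs plus consistency metadata."""

    n_patients: int
    distribution: pd.DataFrame  # variable, level, n, pct
    attrition: dict
    quintile_prevalence: dict[str, pd.DataFrame]
    disparity: dict[str, DisparityTable]
    stratified: dict[str, pd.DataFrame]
    area_aggregates: pd.DataFrame
    extreme_test: dict = field(default_factory=dict)

    def to_manifest(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "attrition": self.attrition,
            "extreme_quintile_test": self.extreme_test,
            "disparity": {
                idx: table.to_frame().to_dict(orient="records")
                for idx, table in self.disparity.items()
            },
        }


def _distribution_block(series: pd.Series, variable: str, levels: list, n: int) -> list[dict]:
    rows = []
    for level in levels:
        count = int((series == level).sum())
        rows.append(
            {
                "variable": variable,
                "level": str(level),
                "n": count,
                "pct": round(100.0 * count / n, 1) if n else float("nan"),
            }
        )
    return rows


def _age_decade(age: float) -> str:
    if age >= 80:
        return "80+"
    lo = int(age // 10) * 10
    return f"{lo}-{lo + 9}"


def export_area_aggregates(
    assignments: pd.DataFrame, k: int = 5
) -> pd.DataFrame:
    """Per-area n and obesity percentage, small cells suppressed.

    Areas with fewer than ``k`` patients are dropped entirely (their
    obesity share would be a small-cell disclosure risk).
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    rows = []
    for area, sub in assignments.groupby("area_id", sort=True):
        if len(sub) < k:
            continue
        obese = int((sub["bmi_category"] == "obese").sum())
        rows.append(
            {
                "area_id": area,
                "n": len(sub),
                "obese_pct": round(100.0 * obese / len(sub), 1),
            }
        )
    return pd.DataFrame(rows, columns=["area_id", "n", "obese_pct"])


def build_report(
    assignments: pd.DataFrame,
    attrition: AttritionReport | dict | None = None,
    k: int = 5,
) -> StudyReport:
    """Assemble the full study report from quintile assignments.

    ``assignments`` carries one row per analysed patient (sex, age,
    age_group, bmi_category, material/social/combined quintiles, urban
    flag, area_id when available).
    """
    n = len(assignments)
    if n and assignments["patient_id"].duplicated().any():
        raise ValueError("duplicate patient ids in assignments")

    dist_rows: list[dict] = []
    if n:
        decades = assignments["age"].map(_age_decade)
        dist_rows += _distribution_block(assignments["sex"], "sex", ["F", "M"], n)
        dist_rows += _distribution_block(decades, "age", list(AGE_BINS), n)
        for idx in ("material", "social", "combined"):
            dist_rows += _distribution_block(
                assignments[f"{idx}_q"], f"{idx}_deprivation", list(QUINTILES), n
            )
        dist_rows += _distribution_block(
            assignments["bmi_category"], "bmi_category", list(BMI_CATEGORIES), n
        )
    distribution = pd.DataFrame(dist_rows, columns=["variable", "level", "n", "pct"])

    # consistency: BMI category counts sum to the sample size
    if n:
        cat_total = int(distribution.loc[distribution["variable"] == "bmi_category", "n"].sum())
        if cat_total != n:
            raise ValueError(f"BMI category counts sum to {cat_total}, expected {n}")

    quint_prev: dict[str, pd.DataFrame] = {}
    disparity: dict[str, DisparityTable] = {}
    stratified: dict[str, pd.DataFrame] = {}
    if n:
        total_obese = int((assignments["bmi_category"] == "obese").sum())
        for idx in ("material", "social", "combined"):
            prev = quintile_prevalences(assignments, index=idx)
            quint_prev[idx] = prev
            if (prev["total"] > 0).all() and prev["prevalence_pct"].iloc[0] > 0:
                disparity[idx] = disparity_measures(tuple(prev["prevalence_pct"]))
        strat_specs = {"age_group": "age_group"}
        if "urban" in assignments.columns:
            strat_specs["urban_rural"] = "urban"
        for name, col in strat_specs.items():
            table = stratified_analysis(assignments, strata=col, index="combined")
            if not table.empty:
                check_stratified_consistency(table, total_obese)
            stratified[name] = table

    area_aggregates = (
        export_area_aggregates(assignments, k=k)
        if n and "area_id" in assignments.columns
        else pd.DataFrame(columns=["area_id", "n", "obese_pct"])
    )

    attrition_dict: dict = {}
    if isinstance(attrition, AttritionReport):
        attrition_dict = attrition.to_dict()
    elif isinstance(attrition, dict):
        attrition_dict = attrition

    return StudyReport(
        n_patients=n,
        distribution=distribution,
        attrition=attrition_dict,
        quintile_prevalence=quint_prev,
        disparity=disparity,
        stratified=stratified,
        area_aggregates=area_aggregates,
    )
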