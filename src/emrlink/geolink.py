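"""Postal-code → dissemination-area linkage and regional deprivation quintiles.

Deprivation scores are defined per dissemination area (the smallest census
geography). Quintile breakpoints are rescaled to the study region: they are
the 20/40/60/80th percentiles of the scores of in-region areas only,
unweighted by population, so each quintile covers 20% of areas (± one area).
Quintile 1 is least deprived, 5 most deprived; a score exactly on a
breakpoint takes the lower quintile.

Generalized postal codes (fewer than 6 characters) link only when every
conversion row they prefix-match agrees on the area; otherwise the patient
is unlinked as ambiguous. Malformed or missing codes are counted as
erroneous, out-of-region codes and areas without a deprivation score are
counted separately.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_POSTAL_RE = re.compile(r"^[A-Z]\d[A-Z]\d[A-Z]\d$")


@dataclass
class LinkageResult:
    """Per-patient linkage outcomes plus loss accounting."""

    links: pd.DataFrame  # patient_id, area_id for linked patients
    counts: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dict(self.counts)


def link_postal_to_area(
    postal_code: str, conversion: pd.DataFrame
) -> tuple[str | None, str]:
    """Resolve one (possibly generalized) postal code.

    Returns ``(area_id, status)`` where status is one of ``linked``,
    ``out_of_region``, ``erroneous``, ``unmatched`` or ``ambiguous``.
    """
    code = "" if postal_code is None or postal_code != postal_code else str(postal_code).strip()
    if not code or code == "*":
        return None, "erroneous"
    if len(code) == 6:
        if not _POSTAL_RE.match(code):
            return None, "erroneous"
        rows = conversion[conversion["postal_code"] == code]
    elif len(code) < 6:
        rows = conversion[conversion["postal_code"].str.startswith(code)]
    else:
        return None, "erroneous"
    if rows.empty:
        return None, "unmatched"
    areas = rows["area_id"].unique()
    if len(areas) > 1:
        return None, "ambiguous"
    if not bool(rows["in_region"].iloc[0]):
        return areas[0], "out_of_region"
    return areas[0], "linked"


def regional_quintiles(scores: np.ndarray | pd.Series) -> np.ndarray:
    """Quintile breakpoints: 20/40/60/80th percentiles of in-region scores."""
    values = np.asarray(scores, dtype=float)
    if np.unique(values).size < 5:
        raise ValueError("need at least 5 distinct in-region area scores")
    return np.percentile(values, [20, 40, 60, 80])


def quintile_of(score: float, breakpoints: np.ndarray) -> int:
    """Quintile 1-5 for a score; exact breakpoint ties take the lower quintile."""
    return int(np.searchsorted(breakpoints, score, side="left")) + 1


def area_quintiles(deprivation: pd.DataFrame, conversion: pd.DataFrame) -> pd.DataFrame:
    """Material/social/combined quintiles for every scored in-region area."""
    in_region_areas = set(conversion.loc[conversion["in_region"].astype(bool), "area_id"])
    scored = deprivation[deprivation["area_id"].isin(in_region_areas)].copy()
    for comp in ("material", "social", "combined"):
        breaks = regional_quintiles(scored[f"{comp}_score"].to_numpy())
        scored[f"{comp}_q"] = [
            quintile_of(s, breaks) for s in scored[f"{comp}_score"].to_numpy()
        ]
    urban = conversion.drop_duplicates("area_id")[["area_id", "urban"]]
    return scored.merge(urban, on="area_id", how="left")


def link_patients(patients: pd.DataFrame, conversion: pd.DataFrame) -> LinkageResult:
    """Link every patient's postal code; count losses by reason."""
    statuses: list[str] = []
    areas: list[str | None] = []
    cache: dict[str, tuple[str | None, str]] = {}
    for code in patients["postal_code"].astype(object):
        key = "" if code is None or code != code else str(code)
        if key not in cache:
            cache[key] = link_postal_to_area(key, conversion)
        area, status = cache[key]
        areas.append(area)
        statuses.append(status)
    out = patients[["patient_id"]].copy()
    out["area_id"] = areas
    out["link_status"] = statuses
    counts = pd.Series(statuses).value_counts().to_dict()
    counts["total"] = len(patients)
    links = out[out["link_status"] == "linked"][["patient_id", "area_id"]]
    return LinkageResult(links=links.reset_index(drop=True), counts=counts)


def assign_quintiles(
    patients: pd.DataFrame,
    linkage: LinkageResult,
    deprivation: pd.DataFrame,
    conversion: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """Attach material/social/combined quintiles to every linked patient.

    Linked patients whose area has no deprivation score are excluded and
    counted (``no_deprivation_score``). Returns the assignment table (one
    row per retained patient) and a loss-accounting dict.
    """
    quintiles = area_quintiles(deprivation, conversion)
    merged = linkage.links.merge(quintiles, on="area_id", how="left")
    unscored = merged["combined_q"].isna()
    counts = dict(linkage.counts)
    counts["no_deprivation_score"] = int(unscored.sum())
    merged = merged[~unscored]
    assignments = merged[
        ["patient_id", "area_id", "material_q", "social_q", "combined_q", "urban"]
    ].copy()
    for col in ("material_q", "social_q", "combined_q", "urban"):
        assignments[col] = assignments[col].astype(int)
    assignments = assignments.merge(
        patients[["patient_id", "sex", "age", "age_group", "bmi", "bmi_category"]],
        on="patient_id",
        how="left",
    )
    counts["assigned"] = len(assignments)
    return assignments.sort_values("patient_id").reset_index(drop=True), counts
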