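"""The BMI cleaning cascade: visit-level observations → one record per patient.

The cascade restricts to active adults (≥20 years with at least one
observation in the study year), removes exact duplicate rows, drops
measurements inside the pregnancy exclusion window (9 months before to
12 months after the estimated date of birth, inclusive), carries the last
height measurement forward to weight-only rows, drops patients missing
height or weight, applies outlier bounds (BMI < 15 or > 50 excluded, the
bounds themselves retained), removes patients whose within-year BMI
variation is anomalously large, and finally keeps each patient's last
in-year measure.

Attrition is counted in unique patients at every stage and telescopes:
remaining_i = remaining_{i-1} - removed_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from emrlink.config import DISEASE_FLAGS

OUTLIER_LOW = 15.0
OUTLIER_HIGH = 50.0

_CASCADE_STAGES = (
    "active_adult",
    "duplicate_rows",
    "pregnancy_window",
    "missing_height_weight",
    "bmi_outliers",
    "within_patient_variation",
)


@dataclass
class AttritionReport:
    """Ordered per-filter patient attrition. Counts telescope."""

    initial_patients: int
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, removed: int, remaining: int, rows_removed: int = 0) -> None:
        prev = self.stages[-1]["remaining"] if self.stages else self.initial_patients
        if remaining != prev - removed:
            raise ValueError(f"attrition does not telescope at stage {name!r}")
        self.stages.append(
            {"stage": name, "removed": removed, "remaining": remaining, "rows_removed": rows_removed}
        )

    @property
    def final_patients(self) -> int:
        return self.stages[-1]["remaining"] if self.stages else self.initial_patients

    def removed_by(self, stage: str) -> int:
        for s in self.stages:
            if s["stage"] == stage:
                return s["removed"]
        raise KeyError(stage)

    def to_dict(self) -> dict:
        return {"initial_patients": self.initial_patients, "stages": self.stages}


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index: weight (kg) divided by height (m) squared."""
    if not weight > 0 or not height > 0:
        raise ValueError("weight and height must be positive")
    return weight / height**2


def categorize_bmi(bmi: float) -> str:
    """WHO adult categories with half-open intervals.

    underweight < 18.5 ≤ normal < 25 ≤ overweight < 30 ≤ obese.
    """
    if bmi < 18.5:
        return "underweight"
    if bmi < 25.0:
        return "normal"
    if bmi < 30.0:
        return "overweight"
    return "obese"


def age_at_year_end(birth_date: str, year: int) -> float:
    """Age in completed years at December 31 of ``year``.

    Accepts generalized birth dates: full ISO date, YYYY-MM, YYYY, or a
    5-year band ``YYYY-YYYY`` (midpoint year used). Suppressed or empty
    values give NaN.
    """
    s = str(birth_date).strip()
    if not s or s == "*" or s.lower() == "nan":
        return float("nan")
    if len(s) == 9 and s[4] == "-" and s[:4].isdigit() and s[5:].isdigit():
        birth_year = (int(s[:4]) + int(s[5:])) // 2
    else:
        birth_year = int(s[:4])
    return float(year - birth_year)


def age_group_of(age: float) -> str:
    if age >= 80:
        return "80+"
    if age >= 60:
        return "60-79"
    if age >= 40:
        return "40-59"
    return "20-39"


def carry_forward_height(observations: pd.DataFrame) -> pd.DataFrame:
    """Fill missing heights with the patient's last height measurement.

    A weight-only row receives the most recent prior height; rows before
    any height measurement receive the patient's most recent height
    overall. Patients with no height anywhere remain height-missing.
    """
    df = observations.copy()
    df["observation_date"] = pd.to_datetime(df["observation_date"])
    df = df.sort_values(["patient_id", "observation_date"], kind="stable")
    grouped = df.groupby("patient_id", sort=False)["height"]
    df["height"] = grouped.ffill()
    # rows still missing: take the patient's latest recorded height
    last_height = grouped.transform("last")
    df["height"] = df["height"].fillna(last_height)
    return df


def exclude_pregnancy_window(
    observations: pd.DataFrame, edb: pd.Timestamp | str | None = None
) -> pd.DataFrame:
    """Drop measurements within [EDB − 9 months, EDB + 12 months], inclusive.

    ``edb`` (the estimated date of birth of the infant) applies to every
    row if given; otherwise each row's ``pregnancy_edb`` field is used.
    Rows without an EDB are never dropped.
    """
    df = observations.copy()
    obs = pd.to_datetime(df["observation_date"])
    if edb is not None:
        edbs = pd.Series(pd.to_datetime(edb), index=df.index)
    elif "pregnancy_edb" in df.columns:
        edbs = pd.to_datetime(df["pregnancy_edb"], errors="coerce")
    else:
        return df
    lo = edbs - pd.DateOffset(months=9)
    hi = edbs + pd.DateOffset(months=12)
    in_window = edbs.notna() & (obs >= lo) & (obs <= hi)
    return df[~in_window]


def select_final_bmi(
    observations: pd.DataFrame,
    year: int,
    outlier_low: float = OUTLIER_LOW,
    outlier_high: float = OUTLIER_HIGH,
) -> dict | None:
    """One patient's final in-year BMI record, or None if nothing survives.

    Deduplicates exact duplicate rows, computes per-row BMI, drops strict
    outliers (< low or > high; the bounds themselves are retained), and
    keeps the latest in-year measure.
    """
    df = observations.drop_duplicates()
    obs = pd.to_datetime(df["observation_date"])
    df = df[(obs.dt.year == year)]
    df = df[df["height"].notna() & df["weight"].notna()]
    if df.empty:
        return None
    bmi = df["weight"].astype(float) / df["height"].astype(float) ** 2
    ok = (bmi >= outlier_low) & (bmi <= outlier_high)
    df = df[ok]
    if df.empty:
        return None
    df = df.assign(_bmi=bmi[ok]).sort_values("observation_date", kind="stable")
    row = df.iloc[-1]
    age = age_at_year_end(row["birth_date"], year)
    final_bmi = float(row["_bmi"])
    return {
        "patient_id": row["patient_id"],
        "sex": row["sex"],
        "age": age,
        "age_group": age_group_of(age),
        "bmi": final_bmi,
        "bmi_category": categorize_bmi(final_bmi),
        "postal_code": row["postal_code"],
        "observation_date": str(row["observation_date"])[:10],
    }


def exclude_high_within_patient_variation(
    bmi_rows: pd.DataFrame, rule: str = "range-z"
) -> pd.Series:
    """Flag patients whose in-year BMI series is inconsistent with itself.

    ``bmi_rows`` holds one row per valid in-year BMI measure with columns
    ``patient_id`` and ``bmi``. Only patients with ≥2 measures can be
    flagged; with fewer than two such patients no one is.

    Rules (the statistic is the patient's in-year range, max − min):

    - ``range-z`` (default): range strictly above mean + 2·SD of the
      cohort's ranges. Flags only the upper tail, so ordinary
      measurement noise survives and rare erratic series are removed.
    - ``range-2sd``: range strictly above 2·SD of the cohort's ranges
      (no centering). With tightly clustered ranges this removes a large
      share of multi-visit patients, so it is not the default.
    - ``bmi-2sd``: range strictly above 2·SD of the cohort's BMI values.
    """
    counts = bmi_rows.groupby("patient_id")["bmi"].size()
    multi = counts[counts >= 2].index
    if len(multi) < 2:
        return pd.Series(False, index=counts.index)
    grp = bmi_rows[bmi_rows["patient_id"].isin(multi)].groupby("patient_id")["bmi"]
    ranges = grp.max() - grp.min()
    if rule == "range-z":
        threshold = float(ranges.mean()) + 2.0 * float(ranges.std(ddof=1))
    elif rule == "range-2sd":
        threshold = 2.0 * float(ranges.std(ddof=1))
    elif rule == "bmi-2sd":
        threshold = 2.0 * float(bmi_rows["bmi"].std(ddof=1))
    else:
        raise ValueError(f"unknown variation rule {rule!r}")
    flags = pd.Series(False, index=counts.index)
    flags.loc[ranges.index[ranges > threshold]] = True
    return flags


def compare_missingness_cohorts(
    with_bmi: pd.DataFrame, without_bmi: pd.DataFrame
) -> pd.DataFrame:
    """Compare the analytic cohort with the patients lacking a valid BMI.

    Binary chronic-disease flags are compared with 2x2 Pearson chi-square
    tests (no continuity correction); age with an unequal-variance
    two-sample t-test. One patient per row is expected in each input.
    """
    if with_bmi.empty or without_bmi.empty:
        raise ValueError("both cohorts must be non-empty")
    rows = []
    for flag in DISEASE_FLAGS:
        col = f"dx_{flag}"
        if col not in with_bmi.columns or col not in without_bmi.columns:
            continue
        a = with_bmi[col].astype(int)
        b = without_bmi[col].astype(int)
        table = np.array(
            [[int(a.sum()), int(len(a) - a.sum())], [int(b.sum()), int(len(b) - b.sum())]]
        )
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            stat, p = float("nan"), float("nan")
        elif table[:, 0].sum() == table.sum() or table[:, 1].sum() == table.sum():
            stat, p = 0.0, 1.0
        else:
            res = stats.chi2_contingency(table, correction=False)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "variable": flag,
                "with_bmi_rate": float(a.mean()),
                "without_bmi_rate": float(b.mean()),
                "statistic": stat,
                "p_value": p,
                "test": "chi-square",
            }
        )
    t = stats.ttest_ind(
        with_bmi["age"].astype(float), without_bmi["age"].astype(float), equal_var=False
    )
    rows.append(
        {
            "variable": "age",
            "with_bmi_rate": float(with_bmi["age"].mean()),
            "without_bmi_rate": float(without_bmi["age"].mean()),
            "statistic": float(t.statistic),
            "p_value": float(t.pvalue),
            "test": "t-test",
        }
    )
    return pd.DataFrame(rows)


def run_cascade(
    observations: pd.DataFrame,
    year: int,
    outlier_low: float = OUTLIER_LOW,
    outlier_high: float = OUTLIER_HIGH,
    duplicates: str = "exact",
    variation_rule: str = "range-z",
    return_rows: bool = False,
):
    """Apply the full cleaning cascade and report per-filter attrition.

    Returns ``(patient_year_records, attrition)`` — and the surviving final
    observation rows too when ``return_rows`` is set. Filter order is fixed:
    active adults, duplicate rows, pregnancy window, height carry-forward,
    missing height/weight, outlier bounds, within-patient variation, final
    in-year measure.
    """
    df = observations.copy()
    df["observation_date"] = pd.to_datetime(df["observation_date"])
    initial = df["patient_id"].nunique()
    attrition = AttritionReport(initial_patients=initial)

    def _remaining() -> int:
        return df["patient_id"].nunique()

    # 1. active adults: age >= 20 at year end and >= 1 in-year observation
    ages = df["birth_date"].map(lambda b: age_at_year_end(b, year))
    adult = ages >= 20.0
    in_year = df["observation_date"].dt.year == year
    active_ids = set(df.loc[adult & in_year, "patient_id"])
    before = _remaining()
    df = df[df["patient_id"].isin(active_ids)]
    attrition.add("active_adult", before - _remaining(), _remaining())

    # 2. duplicate rows (removes rows, not patients). "exact" drops
    # byte-identical rows; "same-day" additionally collapses repeat
    # measurements on one date, keeping the last.
    before_rows = len(df)
    if duplicates == "same-day":
        df = df.drop_duplicates(subset=["patient_id", "observation_date"], keep="last")
    else:
        df = df.drop_duplicates()
    attrition.add("duplicate_rows", 0, _remaining(), rows_removed=before_rows - len(df))

    # 3. pregnancy exclusion window
    before = _remaining()
    df = exclude_pregnancy_window(df)
    # a patient removed here must still have been in-year active before
    df = df[df.groupby("patient_id")["observation_date"].transform(
        lambda s: (s.dt.year == year).any()
    )]
    attrition.add("pregnancy_window", before - _remaining(), _remaining())

    # 4. last-height carry-forward (no attrition)
    df = carry_forward_height(df)

    # 5. missing height or weight: patient needs >= 1 complete in-year row
    before = _remaining()
    complete = df["height"].notna() & df["weight"].notna() & (
        df["observation_date"].dt.year == year
    )
    keep_ids = set(df.loc[complete, "patient_id"])
    df = df[df["patient_id"].isin(keep_ids)]
    attrition.add("missing_height_weight", before - _remaining(), _remaining())

    # 6. BMI outlier bounds on in-year complete rows
    candidates = df[complete.reindex(df.index, fill_value=False)].copy()
    candidates["bmi"] = candidates["weight"].astype(float) / candidates["height"].astype(float) ** 2
    valid = candidates[(candidates["bmi"] >= outlier_low) & (candidates["bmi"] <= outlier_high)]
    before = _remaining()
    keep_ids = set(valid["patient_id"])
    df = df[df["patient_id"].isin(keep_ids)]
    valid = valid[valid["patient_id"].isin(keep_ids)]
    attrition.add("bmi_outliers", before - _remaining(), _remaining())

    # 7. within-patient variation on the surviving in-year BMI series
    flags = exclude_high_within_patient_variation(valid[["patient_id", "bmi"]], rule=variation_rule)
    flagged = set(flags.index[flags])
    before = _remaining()
    df = df[~df["patient_id"].isin(flagged)]
    valid = valid[~valid["patient_id"].isin(flagged)]
    attrition.add("within_patient_variation", before - _remaining(), _remaining())

    # 8. final in-year measure per patient
    valid = valid.sort_values(["patient_id", "observation_date"], kind="stable")
    final_rows = valid.groupby("patient_id", sort=True).tail(1)
    records = []
    for _, row in final_rows.iterrows():
        age = age_at_year_end(row["birth_date"], year)
        records.append(
            {
                "patient_id": row["patient_id"],
                "sex": row["sex"],
                "age": age,
                "age_group": age_group_of(age),
                "bmi": float(row["bmi"]),
                "bmi_category": categorize_bmi(float(row["bmi"])),
                "postal_code": row["postal_code"],
            }
        )
    patients = pd.DataFrame(
        records,
        columns=["patient_id", "sex", "age", "age_group", "bmi", "bmi_category", "postal_code"],
    )
    if return_rows:
        return patients, attrition, final_rows.drop(columns=["bmi"])
    return patients, attrition
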