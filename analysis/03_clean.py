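"""Run the BMI cleaning cascade and report attrition.

Reads the scrubbed observation table, applies the cascade (active adults,
duplicate rows, pregnancy window, last-height carry-forward, missing
measures, outlier bounds, within-patient variation, last in-year measure)
and writes one BMI record per patient plus the attrition report. Also
compares the retained cohort with the patients who lost their BMI record,
chronic-disease flags by chi-square and age by t-test.
"""

import json
from pathlib import Path

import pandas as pd

from emrlink.cleaning import age_at_year_end, compare_missingness_cohorts, run_cascade
from emrlink.config import DISEASE_FLAGS

ROOT = Path(__file__).resolve().parents[1] / "results"
YEAR = 2011


def main() -> None:
    obs = pd.read_csv(ROOT / "pipeline" / "observations_scrubbed.csv",
                      dtype={"postal_code": str})
    patients, attrition = run_cascade(obs, year=YEAR)
    out = ROOT / "pipeline"
    patients.to_csv(out / "patients.csv", index=False)
    (out / "attrition.json").write_text(json.dumps(attrition.to_dict(), indent=2))

    print(f"{attrition.initial_patients} unique patients extracted")
    for stage in attrition.stages:
        print(f"  {stage['stage']:<26s} -{stage['removed']:>4d} patients "
              f"({stage['rows_removed']} rows) -> {stage['remaining']}")
    print(f"{len(patients)} patients with a final {YEAR} BMI "
          f"({100 * len(patients) / attrition.initial_patients:.1f}% of extraction)")

    # missing-data cohort comparison
    per_patient = obs.drop_duplicates("patient_id").copy()
    per_patient["age"] = per_patient["birth_date"].map(lambda b: age_at_year_end(b, YEAR))
    cols = ["age"] + [f"dx_{f}" for f in DISEASE_FLAGS]
    has_bmi = per_patient["patient_id"].isin(patients["patient_id"])
    comparison = compare_missingness_cohorts(
        per_patient.loc[has_bmi, cols], per_patient.loc[~has_bmi, cols]
    )
    comparison.to_csv(out / "missingness_comparison.csv", index=False)
    sig = comparison[comparison["p_value"] < 0.05]["variable"].tolist()
    print(f"cohort comparison: {len(sig)} variables differ at p<0.05: {sig or 'none'}")


if __name__ == "__main__":
    main()
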