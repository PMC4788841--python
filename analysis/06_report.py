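"""Assemble the final study report tables and per-area aggregates.

Builds the sample-distribution table (sex, age decade, quintile shares,
BMI categories), re-runs the consistency-checked stratified and disparity
tables, and exports per-area obesity aggregates with areas under k=5
patients suppressed — the privacy threshold carried over from
de-identification.
"""

import json
from pathlib import Path

import pandas as pd

from emrlink.cleaning import AttritionReport
from emrlink.report import build_report

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    assignments = pd.read_csv(ROOT / "pipeline" / "assignments.csv")
    attrition = json.loads((ROOT / "pipeline" / "attrition.json").read_text())

    report = build_report(assignments, attrition, k=5)
    out = ROOT / "report"
    out.mkdir(parents=True, exist_ok=True)
    report.distribution.to_csv(out / "distribution.csv", index=False)
    for idx, table in report.disparity.items():
        table.to_frame().to_csv(out / f"disparity_{idx}.csv", index=False)
    for name, table in report.stratified.items():
        table.to_csv(out / f"stratified_{name}.csv", index=False)
    report.area_aggregates.to_csv(out / "area_aggregates.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(report.to_manifest(), indent=2, default=float))

    bmi_rows = report.distribution[report.distribution["variable"] == "bmi_category"]
    print(f"report for {report.n_patients} patients")
    print("BMI categories: " + ", ".join(
        f"{r['level']} {r['n']} ({r['pct']}%)" for _, r in bmi_rows.iterrows()))
    n_areas = len(report.area_aggregates)
    print(f"per-area aggregates: {n_areas} areas exported (cells under k=5 suppressed)")


if __name__ == "__main__":
    main()
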