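"""Disparity analysis: prevalences, chi-square tests, stratified tables.

Computes, for each deprivation index (material, social, combined):
per-quintile obesity prevalence, the 12-df quintile x BMI-category
chi-square, the 1-df most-vs-least-deprived test with relative and
absolute differences, and the disparity table (simple difference and rate
ratio vs the least-deprived quintile). Also stratifies the combined-index
analysis by age group and urban/rural status.
"""

import json
from pathlib import Path

import pandas as pd

from emrlink.disparity import (
    disparity_measures,
    extreme_quintile_test,
    pearson_chi_square,
    quintile_category_table,
    quintile_prevalences,
    stratified_analysis,
)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    assignments = pd.read_csv(ROOT / "pipeline" / "assignments.csv")
    out = ROOT / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    for index in ("material", "social", "combined"):
        prev = quintile_prevalences(assignments, index=index)
        disparity = disparity_measures(tuple(prev["prevalence_pct"]))
        table = disparity.to_frame()
        table.insert(1, "obese", prev["obese"])
        table.insert(2, "total", prev["total"])
        table.to_csv(out / f"disparity_{index}.csv", index=False)

        omnibus = pearson_chi_square(quintile_category_table(assignments, index=index).to_numpy())
        q1 = (int(prev.loc[0, "obese"]), int(prev.loc[0, "total"]))
        q5 = (int(prev.loc[4, "obese"]), int(prev.loc[4, "total"]))
        stat, df, p, rel, absdiff = extreme_quintile_test(q1, q5)
        summary[index] = {
            "omnibus_chi_square": omnibus[0], "omnibus_df": omnibus[1], "omnibus_p": omnibus[2],
            "extreme_chi_square": stat, "extreme_p": p,
            "relative_difference_pct": rel, "absolute_difference_pp": absdiff,
            "rate_ratio_q5": disparity.rate_ratios[4],
        }
        print(f"{index:>8s}: prevalence by quintile {list(prev['prevalence_pct'])}; "
              f"Q5/Q1 rate ratio {disparity.rate_ratios[4]:.2f}; "
              f"Q5 vs Q1 chi-square {stat:.2f} (df {df}, p {p:.2g}); "
              f"omnibus chi-square {omnibus[0]:.2f} (df {omnibus[1]})")

    for name, col in (("age_group", "age_group"), ("urban_rural", "urban")):
        table = stratified_analysis(assignments, strata=col, index="combined")
        table.to_csv(out / f"stratified_{name}.csv", index=False)
        flagged = table.loc[table["low_power"], "stratum"].tolist()
        print(f"stratified by {name}: {len(table)} strata"
              + (f"; low power: {flagged}" if flagged else ""))

    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))


if __name__ == "__main__":
    main()
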