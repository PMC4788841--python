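"""Link patients to dissemination areas and assign deprivation quintiles.

Reads the cleaned patient-year records, resolves postal codes through the
conversion table (counting out-of-region, erroneous/missing, unmatched and
ambiguous codes separately), rescales the deprivation index to the region
by taking quintile breakpoints over in-region areas only, and writes the
per-patient quintile assignments.
"""

import json
from pathlib import Path

import pandas as pd

from emrlink.geolink import assign_quintiles, link_patients

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    patients = pd.read_csv(ROOT / "pipeline" / "patients.csv", dtype={"postal_code": str})
    conversion = pd.read_csv(ROOT / "data" / "conversion.csv", dtype={"postal_code": str})
    deprivation = pd.read_csv(ROOT / "data" / "deprivation.csv")

    linkage = link_patients(patients, conversion)
    assignments, counts = assign_quintiles(patients, linkage, deprivation, conversion)
    out = ROOT / "pipeline"
    assignments.to_csv(out / "assignments.csv", index=False)
    (out / "linkage_losses.json").write_text(json.dumps(counts, indent=2, default=int))

    n = counts["total"]
    print(f"{n} patients with a valid BMI entered linkage")
    for reason in ("out_of_region", "erroneous", "unmatched", "ambiguous"):
        if counts.get(reason):
            print(f"  {reason:<18s} {counts[reason]:>4d} ({100 * counts[reason] / n:.1f}%)")
    print(f"  no deprivation score {counts['no_deprivation_score']} "
          f"({100 * counts['no_deprivation_score'] / n:.1f}%)")
    print(f"{counts['assigned']} patients assigned quintiles "
          f"({100 * counts['assigned'] / n:.1f}% of those with BMI)")


if __name__ == "__main__":
    main()
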