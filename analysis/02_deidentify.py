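"""Scrub free text and produce the k-anonymized release table.

Reads results/data/observations.csv, scrubs clinician-name and
health-card-number shapes from the note field, and generalizes the
quasi-identifiers (postal code, birth date, sex) by global recoding until
every equivalence class holds at least k=5 records. The full-resolution
scrubbed table (used for linkage inside the trust boundary) and the
k-anonymized release table are both written under results/pipeline/.
"""

import json
from pathlib import Path

import pandas as pd

from emrlink.config import AnonymizationPolicy
from emrlink.deidentify import generalize_until_k, scrub_free_text

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    obs = pd.read_csv(ROOT / "data" / "observations.csv", dtype={"postal_code": str})
    policy = AnonymizationPolicy(k=5)
    obs["note"] = obs["note"].fillna("").map(lambda t: scrub_free_text(t, policy))
    released, report = generalize_until_k(obs, policy)

    out = ROOT / "pipeline"
    out.mkdir(parents=True, exist_ok=True)
    obs.to_csv(out / "observations_scrubbed.csv", index=False)
    released.to_csv(out / "observations_release.csv", index=False)
    (out / "anonymization_report.json").write_text(
        json.dumps({k: v for k, v in report.to_dict().items()
                    if k != "class_size_distribution"}, indent=2)
    )
    print(f"release table: postal generalization level {report.postal_level}, "
          f"birth-date level {report.dob_level}, {report.n_suppressed} records suppressed")
    print(f"minimum equivalence class size in release: {report.min_class_size} (k={policy.k})")


if __name__ == "__main__":
    main()
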