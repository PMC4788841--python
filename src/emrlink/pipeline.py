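"""End-to-end orchestration: generate → de-identify → clean → link → analyze.

De-identification and geographic linkage pull in opposite directions:
coarsening a postal code below six characters makes it span multiple
dissemination areas and therefore unlinkable. The study design this
pipeline mirrors resolves the tension with a trust boundary: the full
postal code is used for linkage inside the secure environment, free-text
identifiers are scrubbed on extraction, and everything *released* — the
anonymized observation table and all small-cell aggregates — is
generalized / suppressed to the k-anonymity policy. ``run_pipeline``
implements exactly that: the cascade and linkage run on scrubbed,
full-resolution data, while ``PipelineResult.released_observations``
carries the k-anonymized table a data custodian would share.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from emrlink.cleaning import AttritionReport, run_cascade
from emrlink.config import AnonymizationPolicy, SimulationConfig
from emrlink.deidentify import EquivalenceClassReport, generalize_until_k, scrub_free_text
from emrlink.disparity import (
    extreme_quintile_test,
    pearson_chi_square,
    quintile_category_table,
    quintile_prevalences,
)
from emrlink.geolink import assign_quintiles, link_patients
from emrlink.report import StudyReport, build_report
from emrlink.synthetic import SyntheticBundle, generate_bundle


@dataclass
class PipelineResult:
    bundle: SyntheticBundle
    observations: pd.DataFrame  # scrubbed, full resolution (inside trust boundary)
    released_observations: pd.DataFrame  # k-anonymized release table
    anonymization: EquivalenceClassReport
    patients: pd.DataFrame  # cleaned patient-year records
    attrition: AttritionReport
    assignments: pd.DataFrame
    linkage_counts: dict
    report: StudyReport

    def summary(self, index: str = "combined") -> dict:
        """Headline analysis numbers for one deprivation index."""
        prev = quintile_prevalences(self.assignments, index=index)
        q1 = (int(prev.loc[0, "obese"]), int(prev.loc[0, "total"]))
        q5 = (int(prev.loc[4, "obese"]), int(prev.loc[4, "total"]))
        stat, df, p, rel, absdiff = extreme_quintile_test(q1, q5)
        table = quintile_category_table(self.assignments, index=index)
        omni_stat, omni_df, omni_p = pearson_chi_square(table.to_numpy())
        return {
            "index": index,
            "quintile_prevalence_pct": list(prev["prevalence_pct"]),
            "extreme_chi_square": stat,
            "extreme_df": df,
            "extreme_p": p,
            "relative_difference_pct": rel,
            "absolute_difference_pp": absdiff,
            "omnibus_chi_square": omni_stat,
            "omnibus_df": omni_df,
            "omnibus_p": omni_p,
        }


def run_pipeline(
    config: SimulationConfig,
    policy: AnonymizationPolicy | None = None,
) -> PipelineResult:
    """Run the whole study pipeline on one synthetic bundle."""
    policy = policy or AnonymizationPolicy()
    bundle = generate_bundle(config)

    obs = bundle.observations.copy()
    obs["note"] = obs["note"].fillna("").map(lambda t: scrub_free_text(t, policy))
    released, anon_report = generalize_until_k(obs, policy)

    patients, attrition = run_cascade(obs, year=config.year)
    linkage = link_patients(patients, bundle.conversion)
    assignments, counts = assign_quintiles(
        patients, linkage, bundle.deprivation, bundle.conversion
    )
    report = build_report(assignments, attrition, k=policy.k)
    return PipelineResult(
        bundle=bundle,
        observations=obs,
        released_observations=released,
        anonymization=anon_report,
        patients=patients,
        attrition=attrition,
        assignments=assignments,
        linkage_counts=counts,
        report=report,
    )
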