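"""Validated configuration objects for the simulation and de-identification.

``SimulationConfig`` holds the study conditions the synthetic generator
emulates; its defaults mirror the observed composition of a single
primary-care practice sample for calendar year 2011 (sex ratio, age
structure, defect rates, and the material-deprivation obesity gradient).

``AnonymizationPolicy`` defines the k-anonymity threshold, the
generalization hierarchies for the quasi-identifiers, and the free-text
scrub patterns.
"""

from __future__ import annotations

import math
from typing import Literal, Sequence

from pydantic import BaseModel, Field, field_validator, model_validator

#: Age-decade bins used by the generator (lower bound inclusive).
AGE_BINS: tuple[str, ...] = ("20-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+")

#: Four broad age groups used in the stratified analysis.
AGE_GROUPS: tuple[str, ...] = ("20-39", "40-59", "60-79", "80+")

#: WHO adult BMI categories, in increasing BMI order.
BMI_CATEGORIES: tuple[str, ...] = ("underweight", "normal", "overweight", "obese")

#: The eight chronic-disease flags carried on every observation row.
DISEASE_FLAGS: tuple[str, ...] = (
    "diabetes",
    "hypertension",
    "osteoarthritis",
    "depression",
    "copd",
    "dementia",
    "parkinsons",
    "epilepsy",
)


class SimulationConfig(BaseModel):
    """Study conditions for the synthetic EMR / census bundle.

    All proportions are in [0, 1]. ``age_distribution`` must sum to 1 and
    runs over the decades 20-29 ... 70-79 plus 80+. The per-quintile
    obesity prevalences plant the deprivation gradient the disparity
    analysis should recover (quintile 1 = least deprived).
    """

    n_patients: int = Field(default=7186, ge=1)
    year: int = 2011
    seed: int = 0
    sex_ratio: float = Field(default=0.60, ge=0.0, le=1.0, description="proportion female")
    age_distribution: tuple[float, ...] = (0.105, 0.143, 0.192, 0.204, 0.180, 0.116, 0.060)
    visits_per_patient: float = Field(default=4.2, ge=1.0)
    quintile_obesity_prevalence: tuple[float, float, float, float, float] = (
        0.279,
        0.366,
        0.380,
        0.396,
        0.444,
    )
    missing_height_rate: float = Field(default=0.07, ge=0.0, le=1.0)
    missing_weight_rate: float = Field(default=0.07, ge=0.0, le=1.0)
    duplicate_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    outlier_rate: float = Field(default=0.009, ge=0.0, le=1.0)
    pregnancy_rate: float = Field(default=0.04, ge=0.0, le=1.0)
    out_of_region_postal_rate: float = Field(default=0.09, ge=0.0, le=1.0)
    unmatched_da_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    bmi_noise_sd: float = Field(default=0.4, ge=0.0)
    n_dissemination_areas: int = Field(default=200, ge=5)
    urban_fraction: float = Field(default=0.8, ge=0.0, le=1.0)
    # Anthropometry: sex-specific height distributions (metres). The
    # analysed quantity is BMI; weight is back-solved as BMI x height^2.
    height_mean_female: float = 1.62
    height_mean_male: float = 1.76
    height_sd: float = 0.07

    @field_validator("age_distribution")
    @classmethod
    def _age_distribution_sums_to_one(cls, v: Sequence[float]) -> tuple[float, ...]:
        if len(v) != len(AGE_BINS):
            raise ValueError(f"age_distribution needs {len(AGE_BINS)} proportions")
        if any(p < 0 for p in v):
            raise ValueError("age_distribution proportions must be non-negative")
        if not math.isclose(sum(v), 1.0, abs_tol=1e-9):
            raise ValueError("age_distribution must sum to 1 within 1e-9")
        return tuple(v)

    @field_validator("quintile_obesity_prevalence")
    @classmethod
    def _prevalences_open_interval(cls, v: Sequence[float]) -> tuple[float, ...]:
        if any(not (0.0 < p < 1.0) for p in v):
            raise ValueError("quintile_obesity_prevalence values must lie in (0, 1)")
        return tuple(v)


# Generalization hierarchies. Level 0 is the raw value; each later level
# strictly coarsens the previous one; the last level is full suppression.
POSTAL_LEVELS: tuple[str, ...] = ("full", "5char", "4char", "fsa", "suppressed")
DOB_LEVELS: tuple[str, ...] = ("full", "year-month", "year", "5y-band", "suppressed")

#: Token that replaces scrubbed identifiers and suppressed values.
REDACTED = "[REDACTED]"
SUPPRESSED = "*"

#: Default scrub patterns: titled person names (clinician or patient) and
#: health-card-number shapes (10 digits, optionally grouped 4-3-3).
DEFAULT_SCRUB_PATTERNS: tuple[str, ...] = (
    r"\b(?:Dr|Mr|Mrs|Ms|Mx|Prof)\.?\s+[A-Z][A-Za-z'\-]+",
    r"\b\d{4}[\s-]?\d{3}[\s-]?\d{3}\b",
)


class AnonymizationPolicy(BaseModel):
    """k-anonymity policy: threshold, hierarchies, and scrub patterns.

    ``k`` is the minimum equivalence-class size over the quasi-identifiers.
    ``postal_first`` coarsens postal code through its whole hierarchy before
    touching birth date (the default); ``local_recoding`` generalizes only
    the records in under-sized classes instead of the whole column.
    """

    k: int = Field(default=5, ge=2)
    postal_hierarchy: tuple[str, ...] = POSTAL_LEVELS
    dob_hierarchy: tuple[str, ...] = DOB_LEVELS
    quasi_identifiers: tuple[str, ...] = ("postal_code", "birth_date", "sex")
    scrub_patterns: tuple[str, ...] = DEFAULT_SCRUB_PATTERNS
    postal_first: bool = True
    local_recoding: bool = False
    suppress: bool = True

    @model_validator(mode="after")
    def _hierarchies_end_suppressed(self) -> "AnonymizationPolicy":
        if self.postal_hierarchy[-1] != "suppressed" or self.dob_hierarchy[-1] != "suppressed":
            raise ValueError("generalization hierarchies must end in full suppression")
        return self


Sex = Literal["M", "F"]
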