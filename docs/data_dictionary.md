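# Data dictionary

The synthetic generator emits four CSV tables. The first three have the
schema the pipeline consumes; the truth table exists only for validation
and is never read by any pipeline stage.

## observations.csv — visit-level EMR extraction

One row per measurement encounter.

| column | type | description |
|---|---|---|
| `patient_id` | string | opaque patient identifier (`P000123`) |
| `sex` | `F`/`M` | patient sex |
| `birth_date` | ISO date | date of birth; may be generalized (`1960-07`, `1960`, `1960-1964`, `*`) after de-identification |
| `postal_code` | string | 6-character code (letter-digit-letter digit-letter-digit); may be truncated to 5/4/3 characters or `*` after de-identification; empty when missing |
| `height` | float, metres | measured height; empty when not recorded at this visit |
| `weight` | float, kilograms | measured weight; empty when not recorded |
| `observation_date` | ISO date | date of the encounter |
| `dx_diabetes` … `dx_epilepsy` | 0/1 | the eight chronic-condition flags (diabetes, hypertension, osteoarthritis, depression, COPD, dementia, Parkinson's, epilepsy) |
| `note` | string | free text; may contain identifier-shaped strings before scrubbing |
| `pregnancy_edb` | ISO date | estimated date of birth of the infant, for patients with a pregnancy episode; empty otherwise |

## conversion.csv — postal-code conversion table

One row per postal code.

| column | type | description |
|---|---|---|
| `postal_code` | string | full 6-character code |
| `area_id` | string | dissemination-area identifier (`DA00042`) |
| `urban` | 0/1 | urban delivery area (the code's second character is non-zero iff urban) |
| `in_region` | 0/1 | area lies inside the study region boundary |

## deprivation.csv — area deprivation scores

One row per dissemination area that has a score. In-region areas missing
from this table model postal codes that resolve geographically but match
no deprivation score.

| column | type | description |
|---|---|---|
| `area_id` | string | dissemination-area identifier |
| `material_score` | float | material deprivation (education, employment, income); higher = more deprived |
| `social_score` | float | social deprivation (marital status, family structure); higher = more deprived |
| `combined_score` | float | combined index (material + social) |

## truth.csv — hidden ground truth (validation only)

| column | type | description |
|---|---|---|
| `patient_id` | string | patient identifier |
| `area_id` | string | the patient's true home area |
| `true_obese` | 0/1 | planted obesity status |
| `true_material_q` / `true_social_q` / `true_combined_q` | 1–5 or 0 | regional quintile of the home area (0 when the area has no score) |
| `defect` | string | injected defect class: `clean`, `pregnant`, `missing_height`, `missing_weight`, `outlier`, `bad_postal`, `unmatched_da` |

## Derived pipeline tables

**patients.csv** (after cleaning): `patient_id`, `sex`, `age` (years at
December 31 of the study year), `age_group` (20-39/40-59/60-79/80+),
`bmi` (kg/m²), `bmi_category` (underweight/normal/overweight/obese),
`postal_code`.

**assignments.csv** (after linkage): the above plus `area_id`,
`material_q`, `social_q`, `combined_q` (1 = least deprived, 5 = most)
and `urban`.
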