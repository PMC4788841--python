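# Methods

`emrlink` implements a privacy-preserving pipeline for studying area-level
socioeconomic disparities in obesity from primary-care electronic medical
records (EMRs): de-identification of a visit-level extraction, a BMI
cleaning cascade, postal-code linkage to census dissemination areas with a
regionally rescaled deprivation index, and disparity statistics. Because
patient-level EMR data cannot be published, the pipeline is exercised
end-to-end on a seeded synthetic emulation of the study tables with a
plantable deprivation→obesity gradient, so every stage is testable against
known ground truth.

## The synthetic study population

`SimulationConfig` fixes the study conditions. Defaults describe a single
urban-centred primary-care practice in calendar year 2011:

| parameter | default | meaning |
|---|---|---|
| `n_patients` | 7186 | unique adult patients extracted |
| `sex_ratio` | 0.60 | proportion female |
| `age_distribution` | (.105,.143,.192,.204,.180,.116,.060) | decade shares 20–29 … 80+ |
| `visits_per_patient` | 4.2 | mean encounters per patient (1 + Poisson) |
| `quintile_obesity_prevalence` | (.279,.366,.380,.396,.444) | planted obesity prevalence by combined-deprivation quintile, least→most deprived |
| `pregnancy_rate` | 0.04 | patients whose in-year measurements all fall in a pregnancy exclusion window |
| `missing_height_rate`, `missing_weight_rate` | 0.07 each | patients never measured for height (resp. weight) |
| `outlier_rate` | 0.009 | patients whose BMI is planted outside 15–50 kg/m² |
| `duplicate_rate` | 0.02 | fraction of rows duplicated verbatim |
| `out_of_region_postal_rate` | 0.09 | cascade survivors with an out-of-region, malformed, or missing postal code (split round-robin) |
| `unmatched_da_rate` | 0.05 | cascade survivors whose area has no deprivation score |
| `bmi_noise_sd` | 0.4 kg/m² | within-patient visit-to-visit measurement noise |
| `n_dissemination_areas` | 200 | scored in-region areas |
| `urban_fraction` | 0.8 | share of areas flagged urban |

Patients are assigned uniformly to scored in-region areas; each area
carries independent standard-normal material and social scores (combined =
material + social), and a patient's true obesity status is Bernoulli with
the prevalence of their area's combined quintile. Heights are sex-specific
normals (F: 1.62 m, M: 1.76 m, SD 0.07) and weights are back-solved as
BMI × height², so the BMI structure is exact up to the visit noise. Base
BMI is drawn per category region with a ~0.2 kg/m² margin from the
30 kg/m² cut-point and the 15/50 bounds so that measurement noise only
rarely flips a planted status; this keeps the planted gradient
recoverable, which is the generator's purpose.

Defect classes are assigned to *disjoint* patient sets with binomially
drawn counts, so each cleaning filter's attrition is directly
calibratable against its configured rate. Geographic defects are drawn
from the set of patients who survive the cleaning cascade, mirroring a
flow where linkage follows cleaning. The truth table (obesity status,
home area, quintiles, defect class) is emitted separately and no pipeline
stage reads it.

What the generator does **not** emulate: real postal geography (codes are
random strings with the urban/rural second-character convention only),
secular BMI trends, practice-level data-quality variation, correlation
between missingness and deprivation or obesity, and chronic-disease flags
correlated with BMI (flags are independent Bernoullis). Passing
parameter-recovery tests therefore shows the pipeline is unbiased under
independent missingness, not that real-world selection effects are
handled.

## De-identification

Free-text notes are scrubbed with irreversible pattern replacement
(titled person names; 10-digit health-card shapes). Quasi-identifiers
(postal code, birth date, sex) are coarsened by **global recoding**: one
generalization level per field for the whole table, walking the postal
hierarchy (6 chars → 5 → 4 → forward sortation area → suppressed) to
exhaustion before the birth-date hierarchy (full date → year-month →
year → 5-year band → suppressed), stopping at the first level where every
equivalence class has ≥ k records (k = 5 by default). Because the walk is
a chain through the lattice, the chosen level is the least-coarse
satisfying level along it. Records still below k at maximal
generalization are suppressed and counted. A per-record (local recoding)
mode and a birth-date-first walk are available on the policy object.

De-identification and geographic linkage are inherently in tension: a
postal code truncated below six characters generally spans multiple
dissemination areas and becomes unlinkable. The pipeline therefore uses a
trust boundary: cleaning and linkage run on the scrubbed full-resolution
table, while the k-anonymized table is produced as the *release* artifact,
and all published aggregates (per-area exports) reuse the same k for
small-cell suppression. A generalized code is still linkable when every
conversion row it prefix-matches agrees on the area; otherwise it is
counted as ambiguous.

## Cleaning cascade

Fixed filter order, attrition counted in unique patients at each step:

1. **active adults** — keep patients aged ≥ 20 at December 31 of the study
   year with ≥ 1 in-year observation. Age is `year − birth_year`
   (generalized birth dates use the year, or a band's midpoint).
2. **duplicate rows** — exact-row duplicates dropped (a same-day collapse
   is available); removes rows, not patients.
3. **pregnancy window** — measurements within [EDB − 9 months,
   EDB + 12 months], endpoints inclusive, are dropped (EDB = estimated
   date of birth of the infant).
4. **height carry-forward** — a weight-only row receives the most recent
   prior height; rows before any height receive the patient's most recent
   height overall. Out-of-year rows remain available as height sources,
   which is why the in-year restriction applies to BMI candidates rather
   than to the raw rows.
5. **missing measures** — patients with no in-year row having both height
   and weight are removed.
6. **outlier bounds** — per-row BMI = weight/height²; rows with BMI < 15
   or > 50 kg/m² are dropped (the bounds themselves are retained);
   patients with no surviving row are removed.
7. **within-patient variation** — among patients with ≥ 2 in-year BMI
   values, a patient is removed when their range (max − min) strictly
   exceeds mean + 2 SD of the cohort's ranges. An uncentered 2·SD
   threshold was considered and rejected: ranges cluster tightly around
   their mean under visit-level noise, so 2·SD falls *below* the bulk of
   the distribution and removes roughly half of all multi-visit patients;
   the centered form removes only the upper tail (≈ 2–3 % under the
   default noise), which matches the filter's purpose of catching rare
   internally inconsistent series. Both alternatives remain available via
   `variation_rule`.
8. **final measure** — each patient's latest in-year BMI becomes their
   record; WHO categories use half-open intervals (underweight < 18.5 ≤
   normal < 25 ≤ overweight < 30 ≤ obese).

The attrition report telescopes by construction and the cascade is
idempotent on its own surviving rows. Patients retained with a BMI are
compared against those who lost theirs: 2×2 Pearson chi-square (no
continuity correction) per chronic-disease flag, Welch t-test for age.

## Regional quintiles and linkage

Quintile breakpoints are the 20/40/60/80th percentiles of the deprivation
scores of **in-region areas only**, unweighted by population — the
"rescaling to the region" step. Each quintile then covers 20 % of areas
(± 1 area); patient-level shares can deviate when residence clusters.
Ties at a breakpoint take the lower (less deprived) quintile. Material,
social and combined quintiles are computed independently from their own
scores; the combined quintile comes from a combined continuous score
rather than from crossing the material and social quintiles. Patients in
areas without a score, with out-of-region, malformed, missing or
ambiguous codes, are excluded with per-reason counts.

## Disparity statistics

Prevalences are reported to one decimal as 100·n/N. The omnibus test is
the Pearson chi-square over the 5 × 4 quintile-by-category table
(12 df); the most-vs-least comparison is the 2×2 chi-square (1 df) with
relative difference 100·(p₅/p₁ − 1) and absolute difference p₅ − p₁ in
percentage points. Disparity tables report the simple difference (one
decimal) and rate ratio (two decimals) of each quintile against the
least-deprived reference. No continuity correction (matching the plain
Pearson convention), no confounder adjustment, and no multiple-testing
correction across strata; stratified tables show each obese cell as a
share of the stratum's obese total and flag strata with any expected
count below 5 as low-power.

## Numerical and validation choices

- All randomness flows from one `numpy.random.default_rng(seed)`;
  identical config + seed reproduces byte-identical tables.
- Percentile breakpoints use NumPy's default linear interpolation.
- Parameter recovery is validated over 20 seeds at n = 5000 under the
  default defect rates: the mean estimated Q5/Q1 rate ratio must sit
  within 3 standard errors (of the seed-to-seed mean) of the planted
  0.444/0.279 ≈ 1.59, and the mean Q5 prevalence within 3 pp of 44.4 %.
- Type-I calibration of the 12-df test draws 1000 null tables
  (multinomial category counts identical across quintiles, n = 5000) and
  requires the rejection rate to be 5 % within 3 Monte-Carlo standard
  errors. The null tables are sampled directly rather than through the
  full generator because the property being calibrated is the test, and
  the direct draw is exact under the null.
- The chi-square implementation is cross-checked in tests against a
  hand-written brute-force evaluation of the Pearson formula on random
  tables up to 6×6.

## Known limitations

- The within-patient-variation threshold is cohort-relative, so its
  attrition share depends on the noise level; with zero noise it removes
  nobody.
- Linkage of generalized codes is conservative (all-areas-agree); a
  probabilistic allocation of generalized codes is out of scope.
- The anonymizer's local-recoding mode is quadratic in table size and
  intended for small extracts.
- Area population weighting of quintile breakpoints is not implemented;
  breakpoints are unweighted area percentiles.
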