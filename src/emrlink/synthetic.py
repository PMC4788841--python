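"""Seeded synthetic EMR / census-linkage bundle.

Emulates the three study tables the pipeline consumes — a visit-level
observation table from a primary-care practice, a postal-code conversion
table, and a dissemination-area deprivation table — plus a truth table
(per-patient obesity status and deprivation quintile) that downstream
stages never see.

The generator plants a deprivation→obesity gradient at the area level:
each patient's true obesity status is Bernoulli with the prevalence of
their area's combined-deprivation quintile. Heights are drawn from
sex-specific normal distributions and weights back-solved as
BMI x height^2 so the BMI structure is exact up to measurement noise.

Injected defects (pregnancy episodes, missing heights/weights, outlier
BMIs, duplicate rows, out-of-region / erroneous / missing postal codes,
postal codes whose area lacks a deprivation score) are assigned to
disjoint patient sets at the configured rates, so each cleaning filter's
attrition is directly calibratable.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from emrlink.config import AGE_BINS, DISEASE_FLAGS, SimulationConfig

# First letters valid in Canadian forward sortation areas.
_FSA_LETTERS = "ABCEGHJKLMNPRSTVXY"

_SURNAMES = ("Smith", "Chen", "Tremblay", "Patel", "MacDonald", "Nguyen", "Roy", "Singh")

_AGE_BOUNDS = {
    "20-29": (20, 29),
    "30-39": (30, 39),
    "40-49": (40, 49),
    "50-59": (50, 59),
    "60-69": (60, 69),
    "70-79": (70, 79),
    "80+": (80, 95),
}

# Disease-flag base prevalences for the chronic-condition indicators.
_FLAG_PREVALENCE = {
    "diabetes": 0.12,
    "hypertension": 0.25,
    "osteoarthritis": 0.11,
    "depression": 0.15,
    "copd": 0.18,
    "dementia": 0.03,
    "parkinsons": 0.01,
    "epilepsy": 0.015,
}


@dataclass
class SyntheticBundle:
    """The three pipeline inputs plus the hidden truth table."""

    observations: pd.DataFrame
    conversion: pd.DataFrame
    deprivation: pd.DataFrame
    truth: pd.DataFrame

    def write(self, directory: str | Path) -> None:
        """Write the four tables as CSV under ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.observations.to_csv(directory / "observations.csv", index=False)
        self.conversion.to_csv(directory / "conversion.csv", index=False)
        self.deprivation.to_csv(directory / "deprivation.csv", index=False)
        self.truth.to_csv(directory / "truth.csv", index=False)


def generate_postal_code(area_id: str, urban: bool, rng: np.random.Generator) -> str:
    """One 6-character postal code (letter-digit-letter digit-letter-digit).

    The second character encodes urban/rural the way the national postal
    system does: '0' marks a rural delivery area, 1-9 urban.
    """
    letters = rng.choice(list(_FSA_LETTERS), size=3)
    second = "0" if not urban else str(rng.integers(1, 10))
    digits = rng.integers(0, 10, size=2)
    return f"{letters[0]}{second}{letters[1]}{digits[0]}{letters[2]}{digits[1]}"


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size: int
) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds are a few sd wide here)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def _draw_base_bmi(rng: np.random.Generator, obese: np.ndarray) -> np.ndarray:
    """Patient-level BMI consistent with planted obesity status.

    Category regions keep a small margin from the 30 kg/m^2 cut-point and
    the 15/50 outlier bounds so visit-level measurement noise only rarely
    flips the planted status.
    """
    n = len(obese)
    bmi = np.empty(n)
    n_ob = int(obese.sum())
    bmi[obese] = _truncated_normal(rng, 34.0, 3.5, 30.2, 49.5, n_ob)
    # Non-obese mixture: underweight / normal / overweight shares typical
    # of an adult primary-care population.
    n_no = n - n_ob
    cat = rng.choice(3, size=n_no, p=(0.027, 0.495, 0.478))
    vals = np.empty(n_no)
    vals[cat == 0] = _truncated_normal(rng, 17.5, 1.0, 15.3, 18.4, int((cat == 0).sum()))
    vals[cat == 1] = _truncated_normal(rng, 22.5, 1.8, 18.6, 24.9, int((cat == 1).sum()))
    vals[cat == 2] = _truncated_normal(rng, 27.0, 1.4, 25.1, 29.8, int((cat == 2).sum()))
    bmi[~obese] = vals
    return bmi


def _quintile_breaks(scores: np.ndarray) -> np.ndarray:
    # 20/40/60/80th percentiles; mirrors geolink.regional_quintiles but kept
    # local so the generator stays independent of pipeline code paths.
    return np.percentile(scores, [20, 40, 60, 80])


def _quintile(score: float, breaks: np.ndarray) -> int:
    # ties at a breakpoint take the lower quintile
    return int(np.searchsorted(breaks, score, side="left")) + 1


def _random_day_in_year(rng: np.random.Generator, year: int, size: int) -> list[date]:
    start = date(year, 1, 1)
    n_days = (date(year, 12, 31) - start).days + 1
    return [start + timedelta(days=int(d)) for d in rng.integers(0, n_days, size=size)]


def generate_bundle(config: SimulationConfig) -> SyntheticBundle:
    """Generate the full synthetic bundle for one seed.

    Deterministic for a fixed ``config`` (including its ``seed``).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    # ---- dissemination areas and deprivation scores -------------------
    n_in = config.n_dissemination_areas
    n_unmatched = max(2, n_in // 20)  # in-region areas missing a score
    n_out = max(3, n_in // 10)  # out-of-region areas
    area_ids = [f"DA{i:05d}" for i in range(n_in + n_unmatched + n_out)]
    in_region = np.array([i < n_in + n_unmatched for i in range(len(area_ids))])
    urban = rng.random(len(area_ids)) < config.urban_fraction

    material = rng.normal(0.0, 1.0, size=len(area_ids))
    social = rng.normal(0.0, 1.0, size=len(area_ids))
    combined = material + social

    scored = np.arange(len(area_ids)) < n_in  # areas present in the deprivation table
    deprivation = pd.DataFrame(
        {
            "area_id": np.array(area_ids)[scored],
            "material_score": np.round(material[scored], 4),
            "social_score": np.round(social[scored], 4),
            "combined_score": np.round(combined[scored], 4),
        }
    )

    # ---- postal-code conversion table ---------------------------------
    conv_rows: list[tuple[str, str, int, int]] = []
    seen: set[str] = set()
    area_postals: dict[str, list[str]] = {}
    for idx, aid in enumerate(area_ids):
        codes = []
        for _ in range(3):
            code = generate_postal_code(aid, bool(urban[idx]), rng)
            while code in seen:
                code = generate_postal_code(aid, bool(urban[idx]), rng)
            seen.add(code)
            codes.append(code)
            conv_rows.append((code, aid, int(urban[idx]), int(in_region[idx])))
        area_postals[aid] = codes
    conversion = pd.DataFrame(conv_rows, columns=["postal_code", "area_id", "urban", "in_region"])

    # Quintile truth over the scored (in-region, deprivation-matched) areas.
    breaks_m = _quintile_breaks(material[:n_in])
    breaks_s = _quintile_breaks(social[:n_in])
    breaks_c = _quintile_breaks(combined[:n_in])

    # ---- patients ------------------------------------------------------
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    bin_idx = rng.choice(len(AGE_BINS), size=n, p=config.age_distribution)
    ages = np.array(
        [rng.integers(_AGE_BOUNDS[AGE_BINS[b]][0], _AGE_BOUNDS[AGE_BINS[b]][1] + 1) for b in bin_idx]
    )
    birth_dates = [
        date(config.year - int(a), int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        for a in ages
    ]

    # Patients live in scored areas; geographic defects reassign below.
    patient_area_idx = rng.integers(0, n_in, size=n)

    home_combined_q = np.array([_quintile(combined[i], breaks_c) for i in patient_area_idx])
    prev = np.asarray(config.quintile_obesity_prevalence)
    obese = rng.random(n) < prev[home_combined_q - 1]

    base_bmi = _draw_base_bmi(rng, obese)
    height = np.where(
        sex == "F",
        rng.normal(config.height_mean_female, config.height_sd, size=n),
        rng.normal(config.height_mean_male, config.height_sd, size=n),
    ).clip(1.40, 2.10)

    # ---- defect assignment (disjoint patient sets) ---------------------
    order = rng.permutation(n)
    assigned = np.full(n, "clean", dtype=object)

    def _take(label: str, count: int, eligible: np.ndarray) -> None:
        pool = [i for i in order if assigned[i] == "clean" and eligible[i]]
        for i in pool[:count]:
            assigned[i] = label

    everyone = np.ones(n, dtype=bool)
    _take("pregnant", rng.binomial(n, config.pregnancy_rate), sex == "F")
    _take("missing_height", rng.binomial(n, config.missing_height_rate), everyone)
    _take("missing_weight", rng.binomial(n, config.missing_weight_rate), everyone)
    _take("outlier", rng.binomial(n, config.outlier_rate), everyone)

    # Geographic losses hit patients who survive the cleaning cascade,
    # mirroring a study flow where linkage follows BMI cleaning.
    clean_mask = assigned == "clean"
    n_clean = int(clean_mask.sum())
    _take("bad_postal", rng.binomial(n_clean, config.out_of_region_postal_rate), everyone)
    clean_mask = assigned == "clean"
    _take("unmatched_da", rng.binomial(int(clean_mask.sum()), config.unmatched_da_rate), everyone)

    # Outlier patients get an out-of-bounds base BMI (below 15 or above 50).
    out_idx = np.flatnonzero(assigned == "outlier")
    if out_idx.size:
        lows = rng.random(out_idx.size) < 0.5
        base_bmi[out_idx] = np.where(
            lows,
            rng.uniform(10.0, 14.4, size=out_idx.size),
            rng.uniform(50.7, 60.0, size=out_idx.size),
        )

    # Unmatched-DA patients move to in-region areas without a score;
    # bad-postal patients get an out-of-region, malformed, or empty code.
    unmatched_area_idx = np.arange(n_in, n_in + n_unmatched)
    out_area_idx = np.arange(n_in + n_unmatched, len(area_ids))
    for i in np.flatnonzero(assigned == "unmatched_da"):
        patient_area_idx[i] = rng.choice(unmatched_area_idx)

    patient_postal = np.array(
        [area_postals[area_ids[ai]][rng.integers(0, 3)] for ai in patient_area_idx],
        dtype=object,
    )
    for j, i in enumerate(np.flatnonzero(assigned == "bad_postal")):
        kind = j % 3
        if kind == 0:  # resolvable but out of region
            ai = int(rng.choice(out_area_idx))
            patient_area_idx[i] = ai
            patient_postal[i] = area_postals[area_ids[ai]][rng.integers(0, 3)]
        elif kind == 1:  # malformed
            patient_postal[i] = "".join(rng.choice(list("0123456789"), size=6))
        else:  # missing
            patient_postal[i] = ""

    # ---- visit-level observation rows ----------------------------------
    pregnant_idx = set(np.flatnonzero(assigned == "pregnant"))
    n_visits = 1 + rng.poisson(max(config.visits_per_patient - 1.0, 0.0), size=n)
    rows: list[dict] = []
    flags_per_patient = {
        f: rng.random(n) < _FLAG_PREVALENCE[f] for f in DISEASE_FLAGS
    }

    for i in range(n):
        pid = f"P{i:06d}"
        edb: date | None = None
        if i in pregnant_idx:
            edb = _random_day_in_year(rng, config.year, 1)[0]
        visits = _random_day_in_year(rng, config.year, int(n_visits[i]))
        if edb is not None:
            # keep every in-year visit inside the exclusion window so the
            # pregnancy filter removes the whole patient (the cohort the
            # study excluded outright)
            lo = max(date(config.year, 1, 1), edb - timedelta(days=270))
            hi = min(date(config.year, 12, 31), edb + timedelta(days=365))
            span = (hi - lo).days
            visits = [lo + timedelta(days=int(d)) for d in rng.integers(0, span + 1, size=len(visits))]
        visits.sort()

        note = ""
        if rng.random() < 0.1:
            note = f"seen by Dr. {rng.choice(_SURNAMES)}"
            if rng.random() < 0.3:
                hc = rng.integers(0, 10, size=10)
                note += f", HC {''.join(map(str, hc[:4]))}-{''.join(map(str, hc[4:7]))}-{''.join(map(str, hc[7:]))}"

        record_height = assigned[i] != "missing_height"
        record_weight = assigned[i] != "missing_weight"
        for v, obs_date in enumerate(visits):
            visit_bmi = base_bmi[i] + rng.normal(0.0, config.bmi_noise_sd)
            # height recorded at the first visit and sporadically after,
            # exercising last-height carry-forward
            has_height = record_height and (v == 0 or rng.random() < 0.3)
            rows.append(
                {
                    "patient_id": pid,
                    "sex": sex[i],
                    "birth_date": birth_dates[i].isoformat(),
                    "postal_code": patient_postal[i],
                    "height": round(float(height[i]), 3) if has_height else None,
                    "weight": round(float(visit_bmi * height[i] ** 2), 1) if record_weight else None,
                    "observation_date": obs_date.isoformat(),
                    **{f"dx_{f}": int(flags_per_patient[f][i]) for f in DISEASE_FLAGS},
                    "note": note if v == 0 else "",
                    "pregnancy_edb": edb.isoformat() if edb is not None else "",
                }
            )

    observations = pd.DataFrame(rows)

    # exact duplicate rows at the configured rate
    n_dup = rng.binomial(len(observations), config.duplicate_rate)
    if n_dup:
        dup_rows = observations.iloc[rng.integers(0, len(observations), size=n_dup)]
        observations = pd.concat([observations, dup_rows], ignore_index=True)
        observations = observations.iloc[rng.permutation(len(observations))].reset_index(drop=True)

    # Truth quintiles follow the patient's final area; 0 where the area has
    # no deprivation score (out-of-region or unmatched).
    scored_area = patient_area_idx < n_in
    material_q = np.where(
        scored_area, [_quintile(material[i], breaks_m) for i in patient_area_idx], 0
    )
    social_q = np.where(
        scored_area, [_quintile(social[i], breaks_s) for i in patient_area_idx], 0
    )
    combined_q = np.where(
        scored_area, [_quintile(combined[i], breaks_c) for i in patient_area_idx], 0
    )
    truth = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "area_id": [area_ids[ai] for ai in patient_area_idx],
            "true_obese": obese.astype(int),
            "true_material_q": material_q,
            "true_social_q": social_q,
            "true_combined_q": combined_q,
            "defect": assigned,
        }
    )

    return SyntheticBundle(observations, conversion, deprivation, truth)
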