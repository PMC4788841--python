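"""Postal-code linkage and regional quintile rescaling."""

import numpy as np
import pandas as pd
import pytest

from emrlink.geolink import (
    area_quintiles,
    assign_quintiles,
    link_patients,
    link_postal_to_area,
    quintile_of,
    regional_quintiles,
)


@pytest.fixture()
def conversion():
    return pd.DataFrame(
        {
            "postal_code": ["K7M1A1", "K7M1A2", "K7M9Z9", "K7L5B5", "X0X0X0"],
            "area_id": ["DA1", "DA1", "DA2", "DA3", "DA9"],
            "urban": [1, 1, 1, 1, 0],
            "in_region": [1, 1, 1, 1, 0],
        }
    )


# ----------------------------------------------------------------- linkage


def test_exact_in_region_code_links(conversion):
    assert link_postal_to_area("K7M1A1", conversion) == ("DA1", "linked")


def test_absent_code_is_unmatched(conversion):
    assert link_postal_to_area("K7M1B9", conversion) == (None, "unmatched")


def test_out_of_region_code_counted_separately(conversion):
    area, status = link_postal_to_area("X0X0X0", conversion)
    assert status == "out_of_region"


@pytest.mark.parametrize("code", ["", "*", "123456", "K7M1A", "K7M1A1X"])
def test_malformed_or_generalized_handling(code, conversion):
    area, status = link_postal_to_area(code, conversion)
    if code == "K7M1A":  # generalized 5-char prefix, unique area
        assert (area, status) == ("DA1", "linked")
    else:
        assert area is None


def test_generalized_code_spanning_two_areas_is_ambiguous(conversion):
    # FSA "K7M" prefixes codes in DA1 and DA2
    area, status = link_postal_to_area("K7M", conversion)
    assert area is None and status == "ambiguous"


def test_link_patients_counts_every_reason(conversion):
    patients = pd.DataFrame(
        {
            "patient_id": ["P1", "P2", "P3", "P4", "P5"],
            "postal_code": ["K7M1A1", "X0X0X0", "BADCODE", "K7M1B9", ""],
        }
    )
    result = link_patients(patients, conversion)
    assert result.counts["linked"] == 1
    assert result.counts["out_of_region"] == 1
    assert result.counts["erroneous"] == 2  # malformed + missing
    assert result.counts["unmatched"] == 1
    assert list(result.links["patient_id"]) == ["P1"]


# ---------------------------------------------------------------- quintiles


def test_quintiles_over_1_to_100():
    breaks = regional_quintiles(np.arange(1, 101))
    assert quintile_of(50, breaks) == 3
    assert quintile_of(1, breaks) == 1
    assert quintile_of(100, breaks) == 5


def test_exact_breakpoint_takes_lower_quintile():
    scores = np.arange(1.0, 101.0)
    breaks = regional_quintiles(scores)
    assert quintile_of(float(breaks[0]), breaks) == 1
    assert quintile_of(float(breaks[0]) + 1e-9, breaks) == 2


def test_too_few_distinct_scores_rejected():
    with pytest.raises(ValueError):
        regional_quintiles(np.array([1.0, 1.0, 2.0, 3.0, 4.0]))


def test_quintile_occupancy_is_balanced():
    """Each quintile holds 20% of areas, within one area."""
    rng = np.random.default_rng(3)
    for n in (50, 101, 237):
        scores = rng.normal(size=n)
        breaks = regional_quintiles(scores)
        qs = np.array([quintile_of(s, breaks) for s in scores])
        counts = np.bincount(qs, minlength=6)[1:]
        assert counts.max() - counts.min() <= 2
        assert all(abs(c - n / 5) <= 1 for c in counts)


def test_only_in_region_areas_define_breakpoints():
    """Out-of-region areas must not shift the regional quintile scale."""
    conv = pd.DataFrame(
        {
            "postal_code": [f"K7M1A{i}" for i in range(10)] + ["X0X0X0"],
            "area_id": [f"DA{i}" for i in range(10)] + ["DAX"],
            "urban": 1,
            "in_region": [1] * 10 + [0],
        }
    )
    dep = pd.DataFrame(
        {
            "area_id": [f"DA{i}" for i in range(10)] + ["DAX"],
            "material_score": list(range(10)) + [1000.0],
            "social_score": list(range(10)) + [1000.0],
            "combined_score": list(range(10)) + [1000.0],
        }
    )
    quintiles = area_quintiles(dep, conv)
    assert "DAX" not in set(quintiles["area_id"])
    assert quintiles["combined_q"].max() == 5


# --------------------------------------------------------------- assignment


def _mini_world():
    conv = pd.DataFrame(
        {
            "postal_code": [f"K7M1A{i}" for i in range(5)] + ["K7X9Y9"],
            "area_id": [f"DA{i}" for i in range(5)] + ["DA_NO_SCORE"],
            "urban": [1, 1, 1, 0, 0, 1],
            "in_region": 1,
        }
    )
    dep = pd.DataFrame(
        {
            "area_id": [f"DA{i}" for i in range(5)],
            "material_score": [1.0, 2.0, 3.0, 4.0, 5.0],
            "social_score": [5.0, 4.0, 3.0, 2.0, 1.0],
            "combined_score": [1.0, 2.0, 3.0, 4.0, 5.0],
        }
    )
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(6)],
            "postal_code": [f"K7M1A{i}" for i in range(5)] + ["K7X9Y9"],
            "sex": "F",
            "age": 50.0,
            "age_group": "40-59",
            "bmi": [22.0, 31.0, 24.0, 33.0, 35.0, 28.0],
            "bmi_category": ["normal", "obese", "normal", "obese", "obese", "overweight"],
        }
    )
    return patients, conv, dep


def test_assign_quintiles_end_to_end():
    patients, conv, dep = _mini_world()
    linkage = link_patients(patients, conv)
    assignments, counts = assign_quintiles(patients, linkage, dep, conv)
    assert counts["no_deprivation_score"] == 1
    assert counts["assigned"] == 5
    lowest = assignments[assignments["patient_id"] == "P0"].iloc[0]
    assert lowest["combined_q"] == 1 and lowest["material_q"] == 1
    # material and social run in opposite directions in this fixture
    assert lowest["social_q"] == 5
    highest = assignments[assignments["patient_id"] == "P4"].iloc[0]
    assert highest["combined_q"] == 5


def test_assignment_is_permutation_invariant():
    patients, conv, dep = _mini_world()
    shuffled = patients.sample(frac=1, random_state=9).reset_index(drop=True)
    a1, _ = assign_quintiles(patients, link_patients(patients, conv), dep, conv)
    a2, _ = assign_quintiles(shuffled, link_patients(shuffled, conv), dep, conv)
    pd.testing.assert_frame_equal(a1, a2)


def test_residential_clustering_skews_patient_quintile_shares():
    """Allocating patients preferentially to high-deprivation areas pushes
    the patient-level Q5 share above the 20% area-level share."""
    conv = pd.DataFrame(
        {
            "postal_code": [f"K7M{i}A{i}" for i in range(10)],
            "area_id": [f"DA{i}" for i in range(10)],
            "urban": 1,
            "in_region": 1,
        }
    )
    dep = pd.DataFrame(
        {
            "area_id": [f"DA{i}" for i in range(10)],
            "material_score": np.arange(10.0),
            "social_score": np.arange(10.0),
            "combined_score": np.arange(10.0),
        }
    )
    # 3x as many patients in the two most deprived areas
    alloc = [1] * 8 + [12, 12]
    rows = []
    for area_idx, count in enumerate(alloc):
        for j in range(count):
            rows.append(
                {
                    "patient_id": f"P{area_idx}_{j}",
                    "postal_code": f"K7M{area_idx}A{area_idx}",
                    "sex": "F",
                    "age": 50.0,
                    "age_group": "40-59",
                    "bmi": 25.0,
                    "bmi_category": "overweight",
                }
            )
    patients = pd.DataFrame(rows)
    assignments, _ = assign_quintiles(patients, link_patients(patients, conv), dep, conv)
    q5_share = (assignments["combined_q"] == 5).mean()
    assert q5_share > 0.2


def test_each_linked_patient_gets_exactly_one_quintile():
    patients, conv, dep = _mini_world()
    assignments, _ = assign_quintiles(patients, link_patients(patients, conv), dep, conv)
    assert assignments["patient_id"].is_unique
    for col in ("material_q", "social_q", "combined_q"):
        assert assignments[col].between(1, 5).all()
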