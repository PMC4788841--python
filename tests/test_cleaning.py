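"""BMI arithmetic, the cleaning filters, and the full cascade."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emrlink.cleaning import (
    carry_forward_height,
    categorize_bmi,
    compare_missingness_cohorts,
    compute_bmi,
    exclude_high_within_patient_variation,
    exclude_pregnancy_window,
    run_cascade,
    select_final_bmi,
)
from emrlink.config import DISEASE_FLAGS
from tests.conftest import obs_row

YEAR = 2011


# ------------------------------------------------------------------ bmi math


@pytest.mark.parametrize(
    "weight,height,expected",
    [(86.7, 1.70, 30.0), (53.0, 1.70, 53.0 / 2.89), (64.0, 1.60, 25.0)],
)
def test_compute_bmi(weight, height, expected):
    assert compute_bmi(weight, height) == pytest.approx(expected)


@pytest.mark.parametrize("weight,height", [(0, 1.7), (70, 0), (-5, 1.7), (70, -1)])
def test_compute_bmi_rejects_non_positive(weight, height):
    with pytest.raises(ValueError):
        compute_bmi(weight, height)


@pytest.mark.parametrize(
    "bmi,category",
    [
        (14.0, "underweight"),
        (18.49, "underweight"),
        (18.5, "normal"),
        (24.99, "normal"),
        (25.0, "overweight"),
        (29.99, "overweight"),
        (30.0, "obese"),
        (50.0, "obese"),
    ],
)
def test_categorize_bmi_half_open_intervals(bmi, category):
    assert categorize_bmi(bmi) == category


# ------------------------------------------------------------- carry-forward


def test_carry_forward_uses_most_recent_prior_height():
    df = pd.DataFrame(
        [
            obs_row("P1", "2010-01-01", height=1.70, weight=None),
            obs_row("P1", "2011-03-01", height=1.72, weight=None),
            obs_row("P1", "2011-05-01", height=None, weight=80.0),
        ]
    )
    out = carry_forward_height(df)
    may = out[out["observation_date"] == pd.Timestamp("2011-05-01")]
    assert may["height"].iloc[0] == 1.72


def test_carry_forward_backfills_from_latest_when_no_prior():
    df = pd.DataFrame(
        [
            obs_row("P1", "2011-02-01", height=None, weight=70.0),
            obs_row("P1", "2011-08-01", height=1.65, weight=None),
        ]
    )
    out = carry_forward_height(df)
    feb = out[out["observation_date"] == pd.Timestamp("2011-02-01")]
    assert feb["height"].iloc[0] == 1.65


def test_carry_forward_leaves_complete_and_heightless_rows_alone():
    df = pd.DataFrame(
        [
            obs_row("P1", "2011-02-01", height=1.80, weight=90.0),
            obs_row("P2", "2011-02-01", height=None, weight=70.0),
            obs_row("P2", "2011-08-01", height=None, weight=71.0),
        ]
    )
    out = carry_forward_height(df)
    assert out[out["patient_id"] == "P1"]["height"].iloc[0] == 1.80
    assert out[out["patient_id"] == "P2"]["height"].isna().all()


# ---------------------------------------------------------- pregnancy window


@pytest.mark.parametrize(
    "obs_date,kept",
    [
        ("2010-09-15", False),  # inside: window starts 2010-09-01
        ("2010-09-01", False),  # inclusive lower endpoint
        ("2010-08-15", True),  # before the window
        ("2012-06-01", False),  # inclusive upper endpoint (edb + 12 months)
        ("2012-06-02", True),  # after the window
    ],
)
def test_pregnancy_window_boundaries(obs_date, kept):
    df = pd.DataFrame([obs_row("P1", obs_date, edb="2011-06-01")])
    out = exclude_pregnancy_window(df)
    assert (len(out) == 1) is kept


def test_patient_without_edb_loses_no_rows():
    df = pd.DataFrame([obs_row("P1", "2011-06-01")])
    assert len(exclude_pregnancy_window(df)) == 1


# ------------------------------------------------------------ final-measure


def test_latest_in_year_measure_selected():
    df = pd.DataFrame(
        [
            obs_row("P1", "2011-03-01", height=1.6, weight=27.1 * 2.56),
            obs_row("P1", "2011-11-01", height=1.6, weight=28.4 * 2.56),
        ]
    )
    rec = select_final_bmi(df, YEAR)
    assert rec["bmi"] == pytest.approx(28.4)
    assert rec["bmi_category"] == "overweight"


def test_outlier_bounds_are_strict():
    low = pd.DataFrame([obs_row("P1", "2011-03-01", height=1.6, weight=14.9 * 2.56)])
    assert select_final_bmi(low, YEAR) is None
    at_bound = pd.DataFrame([obs_row("P1", "2011-03-01", height=1.6, weight=50.0 * 2.56)])
    rec = select_final_bmi(at_bound, YEAR)
    assert rec is not None and rec["bmi"] == pytest.approx(50.0)


def test_out_of_year_rows_are_not_selected():
    df = pd.DataFrame([obs_row("P1", "2010-03-01")])
    assert select_final_bmi(df, YEAR) is None


# --------------------------------------------------- within-patient variation


def _bmi_rows(ranges: dict[str, tuple[float, ...]]) -> pd.DataFrame:
    rows = []
    for pid, values in ranges.items():
        rows += [{"patient_id": pid, "bmi": v} for v in values]
    return pd.DataFrame(rows)


def test_equal_ranges_flag_nobody():
    rows = _bmi_rows({f"P{i}": (25.0, 25.0) for i in range(5)})
    assert not exclude_high_within_patient_variation(rows).any()


def test_single_erratic_series_among_quiet_cohort_is_flagged():
    series = {f"P{i:02d}": (25.0, 25.0 + 0.1 * (i % 3)) for i in range(99)}
    series["P99"] = (20.0, 30.0)  # range 10
    rows = _bmi_rows(series)
    flags = exclude_high_within_patient_variation(rows)
    # oracle: recompute the threshold directly from the ranges
    ranges = np.array([max(v) - min(v) for v in series.values()])
    threshold = ranges.mean() + 2 * ranges.std(ddof=1)
    assert 10.0 > threshold
    assert flags["P99"] and flags.sum() == 1


def test_single_visit_patients_are_never_flagged():
    rows = _bmi_rows({"P1": (20.0,), "P2": (45.0,), "P3": (25.0, 25.1), "P4": (26.0, 26.1)})
    flags = exclude_high_within_patient_variation(rows)
    assert not flags["P1"] and not flags["P2"]


def test_fewer_than_two_multi_visit_patients_means_no_flags():
    rows = _bmi_rows({"P1": (20.0, 45.0), "P2": (25.0,)})
    assert not exclude_high_within_patient_variation(rows).any()


# ------------------------------------------------------- cohort comparison


def _cohort(n: int, flag_count: int, mean_age: float) -> pd.DataFrame:
    df = pd.DataFrame({"age": np.linspace(mean_age - 10, mean_age + 10, n)})
    for f in DISEASE_FLAGS:
        df[f"dx_{f}"] = 0
    df.loc[: flag_count - 1, "dx_diabetes"] = 1
    return df


def test_identical_cohorts_give_null_statistics():
    a = _cohort(100, 50, 50.0)
    out = compare_missingness_cohorts(a, a.copy())
    age_row = out[out["variable"] == "age"].iloc[0]
    assert age_row["statistic"] == pytest.approx(0.0)
    assert age_row["p_value"] == pytest.approx(1.0)
    dia = out[out["variable"] == "diabetes"].iloc[0]
    assert dia["statistic"] == pytest.approx(0.0)


def test_flag_difference_matches_hand_computed_chi_square():
    """30/100 vs 50/100 gives the Pearson statistic 8.33 on [[30,70],[50,50]]."""
    out = compare_missingness_cohorts(_cohort(100, 30, 50.0), _cohort(100, 50, 50.0))
    dia = out[out["variable"] == "diabetes"].iloc[0]
    assert dia["statistic"] == pytest.approx(25 / 3, abs=1e-9)
    assert dia["p_value"] == pytest.approx(stats.chi2.sf(25 / 3, 1))


def test_empty_cohort_rejected():
    with pytest.raises(ValueError):
        compare_missingness_cohorts(_cohort(10, 2, 40.0), _cohort(0, 0, 0.0).iloc[:0])


# -------------------------------------------------------------- full cascade


def test_cascade_attrition_matches_constructed_fixture(cascade_fixture):
    df, expected = cascade_fixture
    patients, attrition = run_cascade(df, YEAR)
    assert attrition.initial_patients == expected["initial"]
    for stage in (
        "active_adult",
        "duplicate_rows",
        "pregnancy_window",
        "missing_height_weight",
        "bmi_outliers",
        "within_patient_variation",
    ):
        assert attrition.removed_by(stage) == expected[stage], stage
    dup = next(s for s in attrition.stages if s["stage"] == "duplicate_rows")
    assert dup["rows_removed"] == expected["duplicate_rows_rows"]
    assert len(patients) == expected["final"]


def test_cascade_attrition_telescopes(cascade_fixture):
    df, _ = cascade_fixture
    _, attrition = run_cascade(df, YEAR)
    remaining = attrition.initial_patients
    for stage in attrition.stages:
        remaining -= stage["removed"]
        assert stage["remaining"] == remaining


def test_cascade_output_category_consistent(cascade_fixture):
    df, _ = cascade_fixture
    patients, _ = run_cascade(df, YEAR)
    for _, row in patients.iterrows():
        assert categorize_bmi(row["bmi"]) == row["bmi_category"]
        assert 15.0 <= row["bmi"] <= 50.0
        assert row["age"] >= 20


def test_cascade_is_idempotent(cascade_fixture):
    df, _ = cascade_fixture
    patients, _, final_rows = run_cascade(df, YEAR, return_rows=True)
    again, attrition2 = run_cascade(final_rows, YEAR)
    assert all(s["removed"] == 0 for s in attrition2.stages)
    lhs = patients.sort_values("patient_id").reset_index(drop=True)
    rhs = again.sort_values("patient_id").reset_index(drop=True)
    pd.testing.assert_frame_equal(lhs, rhs, check_dtype=False)


def test_filter_order_matters_on_fixture(cascade_fixture):
    """Running the missing-measure filter before the pregnancy window moves
    the pregnant height-less patient into the missing bucket."""
    df, expected = cascade_fixture
    _, attrition = run_cascade(df, YEAR)
    assert attrition.removed_by("pregnancy_window") == 1

    # permuted order: drop height-less patients first
    permuted = df.copy()
    permuted["observation_date"] = pd.to_datetime(permuted["observation_date"])
    cf = carry_forward_height(permuted)
    has_complete = cf["height"].notna() & cf["weight"].notna()
    complete_ids = set(cf.loc[has_complete, "patient_id"])
    missing_first_removed = permuted["patient_id"].nunique() - len(complete_ids)
    survivors = permuted[permuted["patient_id"].isin(complete_ids)]
    after_preg = exclude_pregnancy_window(survivors)
    pregnancy_removed = survivors["patient_id"].nunique() - after_preg["patient_id"].nunique()
    assert (pregnancy_removed, missing_first_removed) != (
        expected["pregnancy_window"],
        expected["missing_height_weight"],
    )


def test_pregnancy_attrition_calibrated_on_synthetic_bundle():
    from emrlink.config import SimulationConfig
    from emrlink.synthetic import generate_bundle

    cfg = SimulationConfig(n_patients=2500, seed=13)
    bundle = generate_bundle(cfg)
    _, attrition = run_cascade(bundle.observations, year=cfg.year)
    removed = attrition.removed_by("pregnancy_window")
    se = np.sqrt(cfg.pregnancy_rate * (1 - cfg.pregnancy_rate) * cfg.n_patients)
    assert abs(removed - cfg.pregnancy_rate * cfg.n_patients) <= 3 * se
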