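"""Shared fixtures: a small synthetic bundle and the handcrafted cascade table."""

from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

from emrlink.config import DISEASE_FLAGS, SimulationConfig
from emrlink.synthetic import generate_bundle

settings.register_profile("suite", derandomize=True, max_examples=30, deadline=None)
settings.load_profile("suite")

YEAR = 2011


def obs_row(
    pid: str,
    obs_date: str,
    birth: str = "1971-06-15",
    sex: str = "F",
    height: float | None = 1.6,
    weight: float | None = 64.0,
    postal: str = "K7M1A1",
    edb: str = "",
    note: str = "",
) -> dict:
    row = {
        "patient_id": pid,
        "sex": sex,
        "birth_date": birth,
        "postal_code": postal,
        "height": height,
        "weight": weight,
        "observation_date": obs_date,
        "note": note,
        "pregnancy_edb": edb,
    }
    row.update({f"dx_{f}": 0 for f in DISEASE_FLAGS})
    return row


@pytest.fixture(scope="session")
def small_bundle():
    """A 400-patient bundle with the default defect rates."""
    return generate_bundle(SimulationConfig(n_patients=400, seed=42))


def _bmi_weight(bmi: float, height: float = 1.6) -> float:
    return bmi * height**2


@pytest.fixture()
def cascade_fixture() -> tuple[pd.DataFrame, dict]:
    """Handcrafted observation table where each cascade filter bites once.

    14 patients; the expected patient attrition per stage is constructed
    alongside: one under-age patient, one duplicated row (no patient lost),
    one fully pregnancy-windowed patient, one with weights but never a
    height, one outlier (BMI 60), and one erratic multi-visit series
    (range 30 among eight small-range multi-visit patients).
    """
    w = _bmi_weight
    rows = [
        # P01: 19 years old at year end -> active_adult
        obs_row("P01", "2011-05-01", birth="1992-03-01"),
        # P02: exact duplicate pair; patient retained
        obs_row("P02", "2011-03-01", weight=w(24.0)),
        obs_row("P02", "2011-03-01", weight=w(24.0)),
        # P03: pregnant, weight-only rows all inside the exclusion window
        obs_row("P03", "2011-02-01", height=None, weight=w(27.0), edb="2011-06-01"),
        obs_row("P03", "2011-09-01", height=None, weight=w(28.0), edb="2011-06-01"),
        # P04: weights but no height anywhere -> missing
        obs_row("P04", "2011-04-10", height=None, weight=w(26.0)),
        obs_row("P04", "2011-08-10", height=None, weight=w(26.5)),
        # P05: single BMI 60 -> outlier
        obs_row("P05", "2011-07-01", weight=w(60.0)),
        # P06: erratic series, range 30 -> within-patient variation
        obs_row("P06", "2011-01-10", weight=w(16.0)),
        obs_row("P06", "2011-11-10", weight=w(46.0)),
        # P07: height only at first visit; carry-forward to the later row
        obs_row("P07", "2011-01-05", weight=w(25.0)),
        obs_row("P07", "2011-06-05", height=None, weight=w(25.1)),
        # P08: prior-year height-only row, in-year weight-only rows
        obs_row("P08", "2010-12-01", weight=None),
        obs_row("P08", "2011-03-15", height=None, weight=w(22.0)),
        obs_row("P08", "2011-10-15", height=None, weight=w(22.1)),
        # P09-P12: quiet two-visit patients
        obs_row("P09", "2011-02-02", weight=w(31.0)),
        obs_row("P09", "2011-09-02", weight=w(31.2)),
        obs_row("P10", "2011-02-03", weight=w(23.0)),
        obs_row("P10", "2011-09-03", weight=w(23.2)),
        obs_row("P11", "2011-02-04", weight=w(28.0)),
        obs_row("P11", "2011-09-04", weight=w(28.3)),
        obs_row("P12", "2011-02-05", weight=w(19.0)),
        obs_row("P12", "2011-09-05", weight=w(19.3)),
        # P13: BMI exactly 15.0 twice -> retained (bounds inclusive)
        obs_row("P13", "2011-02-06", weight=w(15.0)),
        obs_row("P13", "2011-09-06", weight=w(15.0)),
        # P14: BMI exactly 50.0 twice -> retained
        obs_row("P14", "2011-02-07", weight=w(50.0)),
        obs_row("P14", "2011-09-07", weight=w(50.0)),
    ]
    expected = {
        "initial": 14,
        "active_adult": 1,
        "duplicate_rows": 0,
        "duplicate_rows_rows": 1,
        "pregnancy_window": 1,
        "missing_height_weight": 1,
        "bmi_outliers": 1,
        "within_patient_variation": 1,
        "final": 9,
    }
    return pd.DataFrame(rows), expected
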