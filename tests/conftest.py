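import numpy as np
import pandas as pd
import pytest

from pharmepi import synthdata


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-size draw from the default (confounded, protective) generator."""
    cohort, truth = synthdata.gen_survey_cohort(
        synthdata.SurveyGenParams(n_participants=8_000, seed=42)
    )
    return cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """No exposure effect, no confounding."""
    cohort, truth = synthdata.gen_survey_cohort(
        synthdata.SurveyGenParams(
            n_participants=8_000,
            true_conditional_or=1.0,
            confounding_strength=0.0,
            seed=7,
        )
    )
    return cohort, truth


def _clean_raw_record(i: int) -> dict:
    return {
        "id": i,
        "age": 45,
        "gender": "male",
        "race": "Non-Hispanic White",
        "education": "high school",
        "weight_kg": 80.0,
        "height_m": 1.75,
        "smoking_lifetime_cigarettes_ge_100": "no",
        "sugar": 100.0,
        "caffeine": 150.0,
        "alcohol": 5.0,
        "hypertension_told": "no",
        "diabetes_told": "no",
        "moderate_activity": "yes",
        "rx_last_month": "no",
        "rx_drug_names": "",
        "rx_duration": "",
        "memory_limited": "no",
        "survey_weight": 1000.0,
        "stratum": 1,
        "psu": i % 2,
    }


@pytest.fixture
def clean_raw_record():
    return _clean_raw_record


@pytest.fixture
def exclusion_fixture():
    """Ten raw records: one violating each screening rule plus one clean.

    Returns (frame, expected per-rule removal counts).
    """
    rows = []
    expected = {}
    r = _clean_raw_record(1)
    r["age"] = 17
    rows.append(r)
    expected["age_under_20"] = 1
    r = _clean_raw_record(2)
    r["memory_limited"] = ""
    rows.append(r)
    expected["missing_memory_status"] = 1
    r = _clean_raw_record(3)
    r["rx_last_month"] = ""
    rows.append(r)
    expected["incomplete_medication_data"] = 1
    expected["exposure_contrast_policy"] = 0  # broad contrast removes nobody
    r = _clean_raw_record(4)
    r["sugar"] = np.nan
    rows.append(r)
    expected["missing_nutrition"] = 1
    r = _clean_raw_record(5)
    r["hypertension_told"] = "refused"
    rows.append(r)
    expected["unknown_hypertension_or_diabetes"] = 1
    r = _clean_raw_record(6)
    r["smoking_lifetime_cigarettes_ge_100"] = "dont know"
    rows.append(r)
    expected["unknown_smoking"] = 1
    r = _clean_raw_record(7)
    r["moderate_activity"] = np.nan
    rows.append(r)
    expected["insufficient_activity"] = 1
    r = _clean_raw_record(8)
    r["height_m"] = np.nan
    rows.append(r)
    expected["missing_bmi_inputs"] = 1
    r = _clean_raw_record(9)
    r["survey_weight"] = -5.0
    rows.append(r)
    expected["missing_design_vars"] = 1
    expected["unmappable_race_or_education"] = 0
    rows.append(_clean_raw_record(10))  # the lone survivor
    return pd.DataFrame(rows), expected
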