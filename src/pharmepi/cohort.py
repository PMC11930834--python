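"""Exclusion cascade and covariate recoding for raw survey interview records.

``screen`` turns a raw-interview table into the coded analysis cohort,
applying a fixed, ordered list of exclusion rules and recording each step in
an :class:`ExclusionLedger`.  ``derive_exposure`` and ``derive_outcome``
implement the single-record coding rules the cascade is built from.

Exposure contrast policies
--------------------------
``broad`` (default)
    Controls are all participants not using the target drug, whether or not
    they use other prescription drugs.
``strict``
    Controls are only participants reporting no prescription-drug use in the
    past month; users of other drugs are excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthdata import RACE_LEVELS, EDU_LEVELS

__all__ = [
    "screen",
    "derive_exposure",
    "derive_outcome",
    "recode_race",
    "recode_education",
    "age_bin",
    "bmi_bin",
    "ExclusionLedger",
    "EmptyCohortError",
    "RAW_COLUMNS",
]

RAW_COLUMNS = (
    "id", "age", "gender", "race", "education", "weight_kg", "height_m",
    "smoking_lifetime_cigarettes_ge_100", "sugar", "caffeine", "alcohol",
    "hypertension_told", "diabetes_told", "moderate_activity",
    "rx_last_month", "rx_drug_names", "rx_duration", "memory_limited",
    "survey_weight", "stratum", "psu",
)

_YES = {"yes", "y", "1", "true"}
_NO = {"no", "n", "0", "false"}

_RACE_MAP = {
    "mexican american": "Mexican American",
    "other hispanic": "Other Hispanic",
    "non-hispanic white": "Non-Hispanic White",
    "non hispanic white": "Non-Hispanic White",
    "non-hispanic black": "Non-Hispanic Black",
    "non hispanic black": "Non-Hispanic Black",
    "other race": "Other",
    "other race - including multi-racial": "Other",
    "other": "Other",
}
_EDU_MAP = {
    "below high school": "below high school",
    "less than 9th grade": "below high school",
    "9-11th grade": "below high school",
    "high school": "high school",
    "high school graduate": "high school",
    "high school graduate/ged or equivalent": "high school",
    "above high school": "above high school",
    "some college": "above high school",
    "some college or aa degree": "above high school",
    "college graduate or above": "above high school",
}


class EmptyCohortError(ValueError):
    """Raised when screening leaves no analyzable records."""


@dataclass
class ExclusionLedger:
    """Ordered record of the exclusion cascade: (rule, removed, remaining)."""

    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, rule: str, removed: int, remaining: int) -> None:
        if self.steps and remaining > self.steps[-1][2]:
            raise ValueError("remaining counts must be non-increasing")
        self.steps.append((rule, int(removed), int(remaining)))

    @property
    def n_final(self) -> int:
        return self.steps[-1][2] if self.steps else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["rule", "removed", "remaining"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                [{"rule": r, "removed": x, "remaining": m} for r, x, m in self.steps],
                fh,
                indent=2,
            )


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, (list, tuple, np.ndarray)):
        return len(value) == 0
    if isinstance(value, float) and np.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return pd.isna(value)


def _yes_no(value) -> str:
    """Normalise a yes/no field to 'yes', 'no' or 'missing'."""
    if _is_missing(value):
        return "missing"
    s = str(value).strip().lower()
    if s in _YES:
        return "yes"
    if s in _NO:
        return "no"
    return "missing"  # refused / don't know / unparseable


def derive_outcome(memory_limited) -> str:
    """Code the subjective-memory question: yes → memory_loss, no → none."""
    status = _yes_no(memory_limited)
    if status == "yes":
        return "memory_loss"
    if status == "no":
        return "none"
    return "missing"


def _drug_names(raw_names) -> list[str]:
    if _is_missing(raw_names):
        return []
    if isinstance(raw_names, str):
        parts = [p.strip() for p in raw_names.split(";")]
    else:
        parts = [str(p).strip() for p in raw_names]
    return [p for p in parts if p]


def derive_exposure(
    rx_last_month,
    rx_drug_names,
    drug_name: str = "atorvastatin",
    contrast: str = "broad",
) -> str:
    """Code exposure from the prescription-drug questions.

    Returns ``'exposed'``, ``'control'`` or ``'excluded'``.  Drug matching is
    a case-insensitive substring test on each reported product name, so salt
    suffixes ("ATORVASTATIN CALCIUM") match.
    """
    if contrast not in ("broad", "strict"):
        raise ValueError(f"unknown contrast {contrast!r}")
    status = _yes_no(rx_last_month)
    if status == "missing":
        return "excluded"
    if status == "no":
        return "control"
    names = _drug_names(rx_drug_names)
    if not names:
        return "excluded"  # reported use but no product recorded
    target = drug_name.lower()
    if any(target in n.lower() for n in names):
        return "exposed"
    return "control" if contrast == "broad" else "excluded"


def recode_race(value) -> str | None:
    if _is_missing(value):
        return None
    return _RACE_MAP.get(str(value).strip().lower())


def recode_education(value) -> str | None:
    if _is_missing(value):
        return None
    return _EDU_MAP.get(str(value).strip().lower())


def age_bin(age: float) -> str:
    """Age subgroup bins on integer age: 20–39, 40–60, >60."""
    a = int(age)
    if a <= 39:
        return "20-39"
    if a <= 60:
        return "40-60"
    return ">60"


def bmi_bin(bmi: float) -> str:
    """Standard BMI bins: <25, 25–30 (inclusive), >30."""
    if bmi < 25.0:
        return "<25"
    if bmi <= 30.0:
        return "25-30"
    return ">30"


def _numeric(value) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        return np.nan
    return v


def screen(
    raw: pd.DataFrame,
    drug_name: str = "atorvastatin",
    contrast: str = "broad",
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Apply the ordered exclusion cascade and recode survivors.

    Rules, in order: age under 20 (or missing); missing memory status;
    incomplete medication-use data; exposure-contrast policy exclusions;
    missing nutritional intake; unknown hypertension or diabetes status;
    unknown smoking status; insufficient physical-activity data; missing BMI
    inputs; missing design variables; unmappable race, education or gender text.

    Returns the coded analysis cohort and the per-rule ledger.  Raises
    :class:`EmptyCohortError` on empty input or zero survivors.
    """
    if raw is None or len(raw) == 0:
        raise EmptyCohortError("no input records")
    df = raw.reset_index(drop=True)

    ledger = ExclusionLedger()
    keep = np.ones(len(df), dtype=bool)

    def apply_rule(name: str, violates: np.ndarray) -> None:
        removed = int((keep & violates).sum())
        keep[violates] = False
        ledger.add(name, removed, int(keep.sum()))

    age = df["age"].map(_numeric).to_numpy()
    apply_rule("age_under_20", np.isnan(age) | (age < 20))

    outcome = df["memory_limited"].map(derive_outcome).to_numpy()
    apply_rule("missing_memory_status", outcome == "missing")

    exposure = df.apply(
        lambda r: derive_exposure(
            r["rx_last_month"], r["rx_drug_names"], drug_name, contrast
        ),
        axis=1,
    ).to_numpy()
    rx_status = df["rx_last_month"].map(_yes_no).to_numpy()
    has_names = df["rx_drug_names"].map(lambda v: len(_drug_names(v)) > 0).to_numpy()
    incomplete_rx = (rx_status == "missing") | ((rx_status == "yes") & ~has_names)
    apply_rule("incomplete_medication_data", incomplete_rx)
    # Remaining 'excluded' codes are contrast-policy exclusions (strict only).
    apply_rule("exposure_contrast_policy", (exposure == "excluded") & ~incomplete_rx)

    nutrition = np.column_stack(
        [df[c].map(_numeric).to_numpy() for c in ("sugar", "caffeine", "alcohol")]
    )
    apply_rule("missing_nutrition", np.isnan(nutrition).any(axis=1))

    htn = df["hypertension_told"].map(_yes_no).to_numpy()
    dia = df["diabetes_told"].map(_yes_no).to_numpy()
    apply_rule("unknown_hypertension_or_diabetes", (htn == "missing") | (dia == "missing"))

    smoke = df["smoking_lifetime_cigarettes_ge_100"].map(_yes_no).to_numpy()
    apply_rule("unknown_smoking", smoke == "missing")

    activity = df["moderate_activity"].map(_yes_no).to_numpy()
    apply_rule("insufficient_activity", activity == "missing")

    wkg = df["weight_kg"].map(_numeric).to_numpy()
    hm = df["height_m"].map(_numeric).to_numpy()
    apply_rule("missing_bmi_inputs", np.isnan(wkg) | np.isnan(hm) | (hm <= 0) | (wkg <= 0))

    sw = df["survey_weight"].map(_numeric).to_numpy()
    missing_design = (
        np.isnan(sw)
        | (sw <= 0)
        | df["stratum"].map(_is_missing).to_numpy()
        | df["psu"].map(_is_missing).to_numpy()
    )
    apply_rule("missing_design_vars", missing_design)

    race = df["race"].map(recode_race).to_numpy()
    edu = df["education"].map(recode_education).to_numpy()
    gender = (
        df["gender"].map(lambda v: "" if _is_missing(v) else str(v).strip().lower()).to_numpy()
    )
    apply_rule(
        "unmappable_race_or_education",
        np.array([r is None for r in race])
        | np.array([e is None for e in edu])
        | ~np.isin(gender, ["male", "female"]),
    )

    if not keep.any():
        raise EmptyCohortError("all records excluded by screening")

    idx = np.flatnonzero(keep)
    sub = df.iloc[idx]
    cohort = pd.DataFrame(
        {
            "id": sub["id"].to_numpy(),
            "exposure": exposure[idx],
            "outcome": outcome[idx],
            "age": age[idx],
            "gender": gender[idx],
            "race": race[idx],
            "education": edu[idx],
            "bmi": np.round(wkg[idx] / hm[idx] ** 2, 1),
            "sugar": sub["sugar"].map(_numeric).to_numpy(),
            "caffeine": sub["caffeine"].map(_numeric).to_numpy(),
            "alcohol": sub["alcohol"].map(_numeric).to_numpy(),
            "smoking": np.where(smoke[idx] == "yes", "smoker", "never"),
            "hypertension": (htn[idx] == "yes").astype(int),
            "diabetes": (dia[idx] == "yes").astype(int),
            "moderate_activity": (activity[idx] == "yes").astype(int),
            "survey_weight": sw[idx],
            "stratum": sub["stratum"].to_numpy(),
            "psu": sub["psu"].to_numpy(),
        }
    )
    assert cohort["race"].isin(RACE_LEVELS).all()
    assert cohort["education"].isin(EDU_LEVELS).all()
    return cohort.reset_index(drop=True), ledger
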