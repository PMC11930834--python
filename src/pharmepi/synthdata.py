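"""Synthetic survey microdata and spontaneous-report streams with known ground truth.

Two generators back the whole pipeline:

``gen_survey_cohort``
    An NHANES-like adult cohort with a multistage design (strata, two or more
    PSUs per stratum, log-normal sampling weights) and a deliberately
    confounded protective exposure: age, hypertension and diabetes raise both
    the probability of exposure and the probability of the memory outcome, so
    the crude exposure–outcome odds ratio sits on the opposite side of 1 from
    the planted conditional odds ratio (a Simpson-type reversal).

``gen_reports``
    A FAERS-like stream of spontaneous reports, each carrying a target-drug
    flag and one adverse-event term, with selected terms over-reported among
    drug reports by a known relative reporting ratio.

Every generated dataset is accompanied by a :class:`GroundTruth` record of all
planted parameters, and regeneration from the same parameters is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "SurveyGenParams",
    "ReportGenParams",
    "GroundTruth",
    "gen_survey_cohort",
    "gen_reports",
    "analytic_ror",
    "as_raw_records",
    "POPULATION_TOTAL",
]

#: Weights are scaled so they sum to this population total (US-adult scale).
POPULATION_TOTAL = 85_000_000.0

RACE_LEVELS = (
    "Mexican American",
    "Other Hispanic",
    "Non-Hispanic White",
    "Non-Hispanic Black",
    "Other",
)
EDU_LEVELS = ("below high school", "high school", "above high school")

# Marginal structure of the emulated adult survey population.
_RACE_PROBS = (0.12, 0.07, 0.61, 0.12, 0.08)
_EDU_PROBS = (0.27, 0.24, 0.49)
_P_MALE = 0.58
_P_SMOKER = 0.43
_P_ACTIVE = 0.50
_AGE_MEAN, _AGE_SD = 42.0, 15.0
_BMI_MEAN, _BMI_SD = 27.8, 4.6
_SUGAR_MEAN, _SUGAR_SD = 123.0, 84.0
_CAFFEINE_MEAN, _CAFFEINE_SD = 173.0, 222.0
_ALCOHOL_MEAN, _ALCOHOL_SD = 14.0, 35.0
# Age-linked comorbidity logits (standardised age), ~16% / ~4% marginal.
_HTN_B0, _HTN_BAGE = -2.2, 1.4
_DIA_B0, _DIA_BAGE = -3.6, 1.2


def _check_proportion(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise ValueError(f"{name} must lie in (0, 1), got {value!r}")


@dataclass(frozen=True)
class SurveyGenParams:
    """Conditions for the survey-cohort generator.

    The defaults encode the emulated study population: ~11% exposure
    prevalence, ~4.3% outcome prevalence, a planted conditional odds ratio of
    0.47 for exposure on outcome, and positive confounding through age,
    hypertension and diabetes strong enough to flip the crude association.
    """

    n_participants: int = 20_000
    n_strata: int = 15
    psus_per_stratum: int = 2
    weight_dispersion: float = 0.5
    exposure_prevalence_target: float = 0.11
    true_conditional_or: float = 0.47
    confounding_strength: float = 0.8
    baseline_outcome_prevalence: float = 0.043
    psu_effect_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise ValueError("n_participants must be positive")
        if self.n_strata <= 0:
            raise ValueError("n_strata must be positive")
        if self.psus_per_stratum < 2:
            raise ValueError(
                "psus_per_stratum must be >= 2 (variance estimation needs "
                ">=2 PSUs per stratum)"
            )
        if self.weight_dispersion <= 0:
            raise ValueError("weight_dispersion must be positive")
        if self.true_conditional_or <= 0:
            raise ValueError("true_conditional_or must be positive")
        if self.psu_effect_sd < 0:
            raise ValueError("psu_effect_sd must be non-negative")
        _check_proportion("exposure_prevalence_target", self.exposure_prevalence_target)
        _check_proportion("baseline_outcome_prevalence", self.baseline_outcome_prevalence)


@dataclass(frozen=True)
class ReportGenParams:
    """Conditions for the spontaneous-report generator.

    ``background_event_probs`` defaults to a Zipf(1) distribution over
    ``n_event_terms`` opaque preferred-term-like labels.  Each planted signal
    ``(term, lam)`` multiplies that term's probability among target-drug
    reports by ``lam`` before renormalisation.
    """

    n_reports: int = 200_000
    n_event_terms: int = 50
    drug_report_fraction: float = 0.10
    background_event_probs: tuple[float, ...] | None = None
    event_terms: tuple[str, ...] | None = None
    planted_signals: tuple[tuple[str, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if self.n_event_terms <= 0:
            raise ValueError("n_event_terms must be positive")
        _check_proportion("drug_report_fraction", self.drug_report_fraction)
        if self.background_event_probs is not None:
            p = np.asarray(self.background_event_probs, dtype=float)
            if len(p) != self.n_event_terms:
                raise ValueError("background_event_probs length != n_event_terms")
            if (p <= 0).any():
                raise ValueError("background probabilities must be positive")
            if abs(p.sum() - 1.0) > 1e-8:
                raise ValueError("background_event_probs must sum to 1")
        if self.event_terms is not None and len(self.event_terms) != self.n_event_terms:
            raise ValueError("event_terms length != n_event_terms")
        for term, lam in self.planted_signals:
            if lam <= 0:
                raise ValueError(f"planted lambda for {term!r} must be positive")

    def terms(self) -> tuple[str, ...]:
        if self.event_terms is not None:
            return self.event_terms
        return tuple(f"PT_{i:03d}" for i in range(1, self.n_event_terms + 1))

    def background(self) -> np.ndarray:
        if self.background_event_probs is not None:
            return np.asarray(self.background_event_probs, dtype=float)
        ranks = np.arange(1, self.n_event_terms + 1, dtype=float)
        p = 1.0 / ranks
        return p / p.sum()

    def drug_event_probs(self) -> np.ndarray:
        """Event distribution among target-drug reports after planting."""
        q = self.background().copy()
        terms = self.terms()
        for term, lam in self.planted_signals:
            if term not in terms:
                raise ValueError(f"planted term {term!r} not in vocabulary")
            i = terms.index(term)
            q[i] *= lam
            if q[i] > 1.0:
                raise ValueError(
                    f"lambda={lam} drives probability of {term!r} above 1"
                )
        return q / q.sum()


@dataclass
class GroundTruth:
    """Record of every planted parameter behind one generated dataset."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    realized: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _calibrate_intercept(linear: np.ndarray, target: float) -> float:
    """Intercept making the mean fitted probability equal ``target``."""
    return brentq(lambda b0: _expit(b0 + linear).mean() - target, -30.0, 30.0, xtol=1e-12)


def gen_survey_cohort(params: SurveyGenParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a coded analysis cohort from the planted generative model.

    Exposure and outcome are Bernoulli draws from logistic models sharing the
    confounder score ``z_age + hypertension + diabetes`` with coefficient
    ``confounding_strength``; the outcome model additionally carries
    ``log(true_conditional_or)`` on the exposure indicator.  Each model has its
    own independent mean-zero Gaussian PSU random effect (SD
    ``psu_effect_sd``), inducing intra-cluster correlation without
    cluster-level confounding.  Intercepts are calibrated by root-finding so
    expected exposure and outcome prevalences hit their targets on the drawn
    covariates.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_participants

    age = np.clip(rng.normal(_AGE_MEAN, _AGE_SD, n), 20.0, 85.0)
    age = np.floor(age)  # survey age is reported in whole years
    age_z = (age - _AGE_MEAN) / _AGE_SD
    gender = np.where(rng.random(n) < _P_MALE, "male", "female")
    race = rng.choice(RACE_LEVELS, size=n, p=_RACE_PROBS)
    education = rng.choice(EDU_LEVELS, size=n, p=_EDU_PROBS)
    bmi = np.round(np.clip(rng.normal(_BMI_MEAN, _BMI_SD, n), 15.0, 60.0), 1)

    def _gamma(mean: float, sd: float) -> np.ndarray:
        shape = (mean / sd) ** 2
        return rng.gamma(shape, mean / shape, n)

    sugar = np.round(_gamma(_SUGAR_MEAN, _SUGAR_SD), 1)
    caffeine = np.round(_gamma(_CAFFEINE_MEAN, _CAFFEINE_SD), 1)
    alcohol = np.round(_gamma(_ALCOHOL_MEAN, _ALCOHOL_SD), 1)
    smoking = np.where(rng.random(n) < _P_SMOKER, "smoker", "never")
    moderate_activity = (rng.random(n) < _P_ACTIVE).astype(int)
    hypertension = (rng.random(n) < _expit(_HTN_B0 + _HTN_BAGE * age_z)).astype(int)
    diabetes = (rng.random(n) < _expit(_DIA_B0 + _DIA_BAGE * age_z)).astype(int)

    stratum = rng.integers(0, p.n_strata, n)
    psu = rng.integers(0, p.psus_per_stratum, n)
    u_exposure = rng.normal(0.0, p.psu_effect_sd, (p.n_strata, p.psus_per_stratum))
    u_outcome = rng.normal(0.0, p.psu_effect_sd, (p.n_strata, p.psus_per_stratum))

    confounder = age_z + hypertension + diabetes
    lin_e = p.confounding_strength * confounder + u_exposure[stratum, psu]
    b0_exposure = _calibrate_intercept(lin_e, p.exposure_prevalence_target)
    exposed = (rng.random(n) < _expit(b0_exposure + lin_e)).astype(int)

    log_or = np.log(p.true_conditional_or)
    lin_y = log_or * exposed + p.confounding_strength * confounder + u_outcome[stratum, psu]
    b0_outcome = _calibrate_intercept(lin_y, p.baseline_outcome_prevalence)
    outcome = (rng.random(n) < _expit(b0_outcome + lin_y)).astype(int)

    raw_w = rng.lognormal(0.0, p.weight_dispersion, n)
    weight = raw_w * (POPULATION_TOTAL / raw_w.sum())

    cohort = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "exposure": np.where(exposed == 1, "exposed", "control"),
            "outcome": np.where(outcome == 1, "memory_loss", "none"),
            "age": age,
            "gender": gender,
            "race": race,
            "education": education,
            "bmi": bmi,
            "sugar": sugar,
            "caffeine": caffeine,
            "alcohol": alcohol,
            "smoking": smoking,
            "hypertension": hypertension,
            "diabetes": diabetes,
            "moderate_activity": moderate_activity,
            "survey_weight": weight,
            "stratum": stratum,
            "psu": psu,
        }
    )
    truth = GroundTruth(
        kind="survey_cohort",
        seed=p.seed,
        params=asdict(p),
        realized={
            "log_conditional_or": log_or,
            "b0_exposure": b0_exposure,
            "b0_outcome": b0_outcome,
            "outcome_model": {
                "exposure": log_or,
                "age_z": p.confounding_strength,
                "hypertension": p.confounding_strength,
                "diabetes": p.confounding_strength,
            },
            "empirical_exposure_prevalence": float(exposed.mean()),
            "empirical_outcome_prevalence": float(outcome.mean()),
        },
    )
    return cohort, truth


def gen_reports(params: ReportGenParams) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a spontaneous-report table with planted over-reporting.

    Each report is independently a target-drug report with probability
    ``drug_report_fraction`` and carries exactly one event term: target-drug
    reports draw from the planted (renormalised) distribution, all others from
    the background.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    terms = np.asarray(p.terms(), dtype=object)
    bg = p.background()
    q = p.drug_event_probs()

    is_drug = rng.random(p.n_reports) < p.drug_report_fraction
    n_drug = int(is_drug.sum())
    events = np.empty(p.n_reports, dtype=object)
    idx_drug = rng.choice(len(terms), size=n_drug, p=q)
    idx_other = rng.choice(len(terms), size=p.n_reports - n_drug, p=bg)
    events[is_drug] = terms[idx_drug]
    events[~is_drug] = terms[idx_other]

    reports = pd.DataFrame(
        {
            "report_id": [f"R{i:08d}" for i in range(1, p.n_reports + 1)],
            "is_target_drug": is_drug,
            "event_term": events,
        }
    )
    truth = GroundTruth(
        kind="reports",
        seed=p.seed,
        params={
            "n_reports": p.n_reports,
            "n_event_terms": p.n_event_terms,
            "drug_report_fraction": p.drug_report_fraction,
            "planted_signals": [list(t) for t in p.planted_signals],
            "seed": p.seed,
        },
        realized={
            "analytic_ror": {
                term: analytic_ror(p, term) for term, _ in p.planted_signals
            },
            "n_drug_reports": n_drug,
        },
    )
    return reports, truth


def analytic_ror(params: ReportGenParams, term: str) -> float:
    """Population reporting odds ratio implied by the generator for ``term``.

    With background probability ``p`` and planted probability ``q`` among drug
    reports, the ROR is the odds ratio ``[q/(1-q)] / [p/(1-p)]``.
    """
    terms = params.terms()
    if term not in terms:
        raise ValueError(f"{term!r} not in vocabulary")
    i = terms.index(term)
    pb = params.background()[i]
    q = params.drug_event_probs()[i]
    return (q / (1.0 - q)) / (pb / (1.0 - pb))


def as_raw_records(cohort: pd.DataFrame, drug_name: str = "atorvastatin") -> pd.DataFrame:
    """Re-express a coded cohort in the raw-interview schema.

    Inverse of the screening/recoding stage for complete records: exposed
    participants report prescription-drug use in the past month with a
    salt-suffixed product name containing ``drug_name``; controls report none.
    Height is fixed at 1.70 m and weight back-computed from BMI.
    """
    height = 1.70
    exposed = cohort["exposure"].to_numpy() == "exposed"
    product = drug_name.upper() + " CALCIUM"
    return pd.DataFrame(
        {
            "id": cohort["id"],
            "age": cohort["age"],
            "gender": cohort["gender"],
            "race": cohort["race"],
            "education": cohort["education"],
            "weight_kg": np.round(cohort["bmi"] * height**2, 4),
            "height_m": height,
            "smoking_lifetime_cigarettes_ge_100": np.where(
                cohort["smoking"] == "smoker", "yes", "no"
            ),
            "sugar": cohort["sugar"],
            "caffeine": cohort["caffeine"],
            "alcohol": cohort["alcohol"],
            "hypertension_told": np.where(cohort["hypertension"] == 1, "yes", "no"),
            "diabetes_told": np.where(cohort["diabetes"] == 1, "yes", "no"),
            "moderate_activity": np.where(cohort["moderate_activity"] == 1, "yes", "no"),
            "rx_last_month": np.where(exposed, "yes", "no"),
            "rx_drug_names": np.where(exposed, product, ""),
            "rx_duration": np.where(exposed, "1 year", ""),
            "memory_limited": np.where(cohort["outcome"] == "memory_loss", "yes", "no"),
            "survey_weight": cohort["survey_weight"],
            "stratum": cohort["stratum"],
            "psu": cohort["psu"],
        }
    )
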