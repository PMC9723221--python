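"""Seeded synthetic pediatric emergency-department cohorts.

No public version of the derivation cohort exists, so this module generates
cohorts with the statistical structure the analysis assumes: an age mixture
dominated by under-fives, age-conditional vital signs and anthropometry,
binary signs/symptoms at configurable prevalences, optional pure-noise decoy
predictors, and a composite admission outcome whose latent probability comes
from a known logistic model (by default the published nine-predictor model).
Every downstream stage of the pipeline is therefore testable against known
ground truth.

The latent Bernoulli draw is the composite outcome itself; the disposition
fields (admitted flag, length of stay, early readmission) are then realized
consistently with it, so that re-deriving the outcome from the disposition
fields recovers the latent draw exactly. This guarantees that refitting the
true predictor set on a large generated cohort recovers the generating
coefficients (no outcome misclassification is introduced).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, SchemaError
from .model import PUBLISHED_MODEL, TriageModel
from .preprocess import transform_predictors

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "write_schema",
    "SCHEMA",
]

#: Default age mixture: (low months, high months, weight). Approximates a
#: young LMIC emergency-department cohort, ~89% under five years.
DEFAULT_AGE_MIXTURE = [
    (0.0, 1.0, 0.050),
    (1.0, 12.0, 0.393),
    (12.0, 24.0, 0.252),
    (24.0, 60.0, 0.197),
    (60.0, 120.0, 0.089),
    (120.0, 228.0, 0.019),
]

#: Symptom prevalences: nuisance parameters for pipeline testing.
DEFAULT_SYMPTOM_PREVALENCE = {
    "parent_concern": 0.25,
    "difficulty_breathing": 0.20,
    "oedema": 0.02,
    "pallor": 0.08,
}

#: Machine-readable cohort schema: (column, type, units, allowed range).
SCHEMA = [
    {"column": "patient_id", "type": "string", "units": None, "range": None},
    {"column": "age_months", "type": "float", "units": "months", "range": [0, None]},
    {"column": "sex", "type": "category", "units": None, "range": ["female", "male"]},
    {"column": "heart_rate_bpm", "type": "float", "units": "beats/min", "range": [0, None]},
    {"column": "temperature_c", "type": "float", "units": "degC", "range": [33, 43]},
    {"column": "muac_mm", "type": "float", "units": "mm", "range": [0, None]},
    {"column": "spo2_pct", "type": "float", "units": "%", "range": [50, 100]},
    {"column": "respiratory_rate_bpm", "type": "float", "units": "breaths/min", "range": [0, None]},
    {"column": "parent_concern", "type": "binary", "units": None, "range": [0, 1]},
    {"column": "difficulty_breathing", "type": "binary", "units": None, "range": [0, 1]},
    {"column": "oedema", "type": "binary", "units": None, "range": [0, 1]},
    {"column": "pallor", "type": "binary", "units": None, "range": [0, 1]},
    {"column": "admitted", "type": "binary", "units": None, "range": [0, 1]},
    {"column": "length_of_stay_hours", "type": "float", "units": "hours", "range": [0, None]},
    {"column": "readmitted_within_48h", "type": "binary", "units": None, "range": [0, 1]},
]

REQUIRED_COLUMNS = [s["column"] for s in SCHEMA]


@dataclass
class GeneratorConfig:
    """Settings of the synthetic cohort generator.

    The intercept offset calibrates the marginal event rate: when it is
    ``None`` and ``target_event_rate`` is set, it is solved by bisection on
    the mean latent probability over the generated predictors.
    """

    n_patients: int = 1612
    seed: int = 0
    true_model: TriageModel = field(default_factory=lambda: PUBLISHED_MODEL)
    target_event_rate: float | None = 0.226
    intercept_offset: float | None = None
    noise_predictor_count: int = 0
    noise_prevalence: float = 0.20
    missingness_rate: float = 0.02
    age_mixture: list[tuple[float, float, float]] = field(
        default_factory=lambda: list(DEFAULT_AGE_MIXTURE)
    )
    symptom_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SYMPTOM_PREVALENCE)
    )
    #: fraction of admitted stays that are shorter than 24 h
    short_stay_fraction: float = 0.10
    #: fraction of positive outcomes realized as early readmissions rather
    #: than index admissions (yields ~1.5% readmission among the non-admitted
    #: at the default event rate)
    readmit_fraction_of_positives: float = 0.05

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        if not (0 <= self.missingness_rate < 0.05):
            raise ConfigError("missingness_rate must lie in [0, 0.05)")
        if self.target_event_rate is not None and not (0 < self.target_event_rate < 1):
            raise ConfigError("target_event_rate must lie in (0, 1)")
        if self.noise_predictor_count < 0:
            raise ConfigError("noise_predictor_count must be >= 0")
        if not (0 < self.noise_prevalence < 1):
            raise ConfigError("noise_prevalence must lie in (0, 1)")
        if not (0 <= self.short_stay_fraction < 1):
            raise ConfigError("short_stay_fraction must lie in [0, 1)")
        if not (0 <= self.readmit_fraction_of_positives < 1):
            raise ConfigError("readmit_fraction_of_positives must lie in [0, 1)")
        weights = [w for _, _, w in self.age_mixture]
        if any(w < 0 for w in weights) or sum(weights) <= 0:
            raise ConfigError("age_mixture weights must be >= 0 with positive sum")
        for name, p in self.symptom_prevalence.items():
            if not (0 <= p <= 1):
                raise ConfigError(f"symptom_prevalence[{name!r}] must lie in [0, 1]")


def _draw_ages(rng: np.random.Generator, n: int, mixture) -> np.ndarray:
    lows = np.array([m[0] for m in mixture])
    highs = np.array([m[1] for m in mixture])
    w = np.array([m[2] for m in mixture], dtype=float)
    band = rng.choice(len(mixture), size=n, p=w / w.sum())
    return rng.uniform(lows[band], highs[band])


def _age_conditional(age, young, mid, old):
    """Piecewise (mean, sd) by age band: <12 mo, 12-60 mo, >=60 mo."""
    mean = np.where(age < 12, young[0], np.where(age < 60, mid[0], old[0]))
    sd = np.where(age < 12, young[1], np.where(age < 60, mid[1], old[1]))
    return mean, sd


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate one synthetic cohort table (one row per triage encounter).

    Identical config and seed give a byte-identical table. Predictor
    marginals are drawn from age-conditional pediatric reference ranges
    (slightly shifted toward illness); the admission probability applies the
    configured true model to the transformed predictors exactly as the
    preprocessing stage would.
    """
    config.validate()
    n = config.n_patients
    rng = np.random.default_rng(config.seed)

    age = _draw_ages(rng, n, config.age_mixture)
    sex = np.where(rng.random(n) < 0.485, "female", "male")

    hr_mean, hr_sd = _age_conditional(age, (145, 22), (125, 20), (105, 17))
    heart_rate = np.clip(rng.normal(hr_mean, hr_sd), 40, 260)
    temperature = np.clip(rng.normal(37.6, 1.0, n), 33, 43)
    rr_mean, rr_sd = _age_conditional(age, (42, 13), (34, 10), (26, 8))
    resp_rate = np.clip(rng.normal(rr_mean, rr_sd), 8, 140)
    muac_mean, muac_sd = _age_conditional(age, (132, 15), (145, 16), (170, 22))
    muac = np.clip(rng.normal(muac_mean, muac_sd), 70, 260)
    # left-skewed saturation: 100 minus a Gamma draw, floored at 50
    spo2 = np.clip(100.0 - rng.gamma(1.4, 2.2, n), 50, 100)

    data = {
        "patient_id": [f"P{i:06d}" for i in range(n)],
        "age_months": age,
        "sex": sex,
        "heart_rate_bpm": heart_rate,
        "temperature_c": temperature,
        "muac_mm": muac,
        "spo2_pct": spo2,
        "respiratory_rate_bpm": resp_rate,
    }
    for name, prev in config.symptom_prevalence.items():
        data[name] = (rng.random(n) < prev).astype(int)
    for k in range(1, config.noise_predictor_count + 1):
        data[f"noise_{k}"] = (rng.random(n) < config.noise_prevalence).astype(int)
    cohort = pd.DataFrame(data)

    # latent admission probability through the same transforms as preprocess
    eta = config.true_model.linear_predictor(transform_predictors(cohort))
    offset = config.intercept_offset
    if offset is None:
        if config.target_event_rate is not None:
            offset = _solve_offset(eta, config.target_event_rate)
        else:
            offset = 0.0
    prob = expit(eta + offset)
    positive = rng.random(n) < prob

    # realize disposition fields consistently with the latent outcome
    admitted = np.zeros(n, dtype=int)
    stay = np.full(n, np.nan)
    readmit = np.zeros(n, dtype=int)

    pos_idx = np.flatnonzero(positive)
    readmit_pos = rng.random(pos_idx.size) < config.readmit_fraction_of_positives
    readmit[pos_idx[readmit_pos]] = 1  # sent home, readmitted within 48 h
    long_idx = pos_idx[~readmit_pos]
    admitted[long_idx] = 1
    stay[long_idx] = 24.0 + rng.gamma(1.2, 36.0, long_idx.size)

    # short (<24 h) admissions among the negatives, sized so the configured
    # fraction of all admitted stays is short
    neg_idx = np.flatnonzero(~positive)
    if config.short_stay_fraction > 0 and neg_idx.size:
        p_long = long_idx.size / n
        ssf = config.short_stay_fraction
        rate = min(1.0, (ssf / (1 - ssf)) * p_long / max(neg_idx.size / n, 1e-12))
        short = neg_idx[rng.random(neg_idx.size) < rate]
        admitted[short] = 1
        stay[short] = rng.uniform(2.0, 24.0, short.size)

    cohort["admitted"] = admitted
    cohort["length_of_stay_hours"] = stay
    cohort["readmitted_within_48h"] = readmit

    if config.missingness_rate > 0:
        predictor_cols = [
            c
            for c in cohort.columns
            if c not in ("patient_id", "admitted", "length_of_stay_hours", "readmitted_within_48h")
        ]
        for c in predictor_cols:
            mask = rng.random(n) < config.missingness_rate
            if mask.any():
                col = cohort[c].astype(object) if cohort[c].dtype == object else cohort[c].astype(float)
                col[mask] = np.nan
                cohort[c] = col
    return cohort


def _solve_offset(eta: np.ndarray, target: float) -> float:
    """Bisection on the mean logistic probability; monotone in the offset."""
    lo, hi = -60.0, 60.0
    f = lambda d: float(np.mean(expit(eta + d))) - target
    if f(lo) > 0 or f(hi) < 0:
        raise ConfigError("target_event_rate unreachable with the generated predictors")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV; absent values are empty fields."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, validating the schema.

    Missing required columns raise :class:`SchemaError` listing them;
    unknown columns (other than ``noise_k`` decoys) produce a warning and
    pass through unchanged. Empty fields become absent values, never zero.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort file missing required columns: {missing}")
    known = set(REQUIRED_COLUMNS)
    unknown = [
        c for c in df.columns if c not in known and not c.startswith("noise_")
    ]
    if unknown:
        warnings.warn(f"unknown cohort columns passed through: {unknown}")
    return df


def write_schema(path) -> None:
    """Write the machine-readable cohort schema descriptor as JSON."""
    with open(path, "w") as fh:
        json.dump(SCHEMA, fh, indent=2)
        fh.write("\n")
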