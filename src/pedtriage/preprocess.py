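"""Outcome derivation, imputation, variable transforms and the EPV screen.

The composite admission outcome is positive when a child was admitted for at
least 24 hours, or was readmitted to a facility within 48 hours of being sent
home. Admission of any duration can be counted instead (a robustness
variant), and a strict ``> 24 h`` rule is available behind a flag.

SpO2 is re-expressed as a *virtual shunt*: the equivalent intrapulmonary
shunt fraction implied by the measured saturation under an altitude-adaptive
physiological model, ``VS = 70.103 * log10(101.687 - SpO2) - 55.833``. The
transform linearizes the relationship between saturation and gas-exchange
impairment on the logit scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, DomainError

__all__ = [
    "VirtualShuntParams",
    "OutcomeRule",
    "EpvRule",
    "OUTCOME_COL",
    "DISPOSITION_COLS",
    "virtual_shunt",
    "derive_outcome",
    "add_outcome",
    "impute",
    "transform_predictors",
    "epv_screen",
]

#: Column holding the derived composite outcome.
OUTCOME_COL = "positive_outcome"

#: Disposition fields: never imputed, never used as predictors.
DISPOSITION_COLS = (
    "admitted",
    "length_of_stay_hours",
    "readmitted_within_48h",
    OUTCOME_COL,
)


@dataclass(frozen=True)
class VirtualShuntParams:
    """Constants of the altitude-adaptive virtual shunt transform.

    ``b > 100`` keeps the logarithm finite over the whole SpO2 range.
    """

    a: float = 70.103
    b: float = 101.687
    c: float = 55.833

    def __post_init__(self):
        if self.b <= 100:
            raise DomainError("VirtualShuntParams.b must exceed 100")


DEFAULT_SHUNT = VirtualShuntParams()


def virtual_shunt(spo2, params: VirtualShuntParams = DEFAULT_SHUNT):
    """Virtual shunt fraction equivalent to an SpO2 reading (percent).

    Strictly decreasing in SpO2: lower saturation implies a larger shunt.
    Accepts scalars or arrays; NaN passes through (imputation handles it).

    Raises
    ------
    DomainError
        If any value lies outside [0, 100].
    """
    x = np.asarray(spo2, dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (x < 0) | (x > 100)
    if np.any(bad):
        raise DomainError(
            f"spo2_pct outside [0, 100]: {np.asarray(spo2)[bad][:5].tolist()}"
        )
    out = params.a * np.log10(params.b - x) - params.c
    return float(out) if np.isscalar(spo2) else out


@dataclass(frozen=True)
class OutcomeRule:
    """Rule deriving the composite admission outcome.

    ``count_all_admissions=True`` switches to the robustness variant in which
    any admission is positive regardless of length of stay. ``strict_stay``
    uses ``> min_stay_hours`` instead of the default ``>=``.
    """

    min_stay_hours: float = 24.0
    readmit_window_hours: float = 48.0
    count_all_admissions: bool = False
    strict_stay: bool = False

    def __post_init__(self):
        if self.min_stay_hours <= 0:
            raise DomainError("OutcomeRule.min_stay_hours must be positive")
        if self.readmit_window_hours <= 0:
            raise DomainError("OutcomeRule.readmit_window_hours must be positive")


def derive_outcome(cohort: pd.DataFrame, rule: OutcomeRule = OutcomeRule()) -> np.ndarray:
    """Composite outcome per row: long-enough admission or early readmission.

    Raises
    ------
    DataError
        If a row is admitted but its length of stay is absent.
    """
    admitted = cohort["admitted"].to_numpy(dtype=float)
    stay = cohort["length_of_stay_hours"].to_numpy(dtype=float)
    readmit = cohort["readmitted_within_48h"].to_numpy(dtype=float)

    broken = (admitted == 1) & np.isnan(stay)
    if broken.any():
        ids = cohort.index[broken].tolist()[:10]
        raise DataError(f"admitted rows with absent length_of_stay_hours: {ids}")

    if rule.count_all_admissions:
        long_stay = admitted == 1
    elif rule.strict_stay:
        long_stay = (admitted == 1) & (stay > rule.min_stay_hours)
    else:
        long_stay = (admitted == 1) & (stay >= rule.min_stay_hours)
    return (long_stay | (readmit == 1)).astype(int)


def add_outcome(cohort: pd.DataFrame, rule: OutcomeRule = OutcomeRule()) -> pd.DataFrame:
    """Return a copy of ``cohort`` with the :data:`OUTCOME_COL` column added."""
    out = cohort.copy()
    out[OUTCOME_COL] = derive_outcome(cohort, rule)
    return out


def _is_categorical(col: pd.Series) -> bool:
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        return True
    vals = col.dropna().unique()
    return len(vals) > 0 and set(np.unique(vals)).issubset({0, 1})


def impute(cohort: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Median/mode single imputation of absent predictor values.

    Continuous columns receive the column median; categorical and binary
    columns the column mode (ties broken toward the smaller value).
    Disposition and outcome fields are never imputed. Imputation statistics
    are computed on the full table passed in; pass per-fold slices for
    leakage-free imputation inside cross-validation.

    Raises
    ------
    DataError
        If a column to impute is entirely absent.
    """
    out = cohort.copy()
    if columns is None:
        columns = [
            c
            for c in out.columns
            if c not in DISPOSITION_COLS and c != "patient_id"
        ]
    for name in columns:
        col = out[name]
        if not col.isna().any():
            continue
        if col.isna().all():
            raise DataError(f"column {name!r} has no observed values to impute from")
        if _is_categorical(col):
            fill = col.mode().sort_values().iloc[0]  # smallest modal value
        else:
            fill = col.median()
        out[name] = col.fillna(fill)
    return out


def transform_predictors(
    cohort: pd.DataFrame, shunt: VirtualShuntParams = DEFAULT_SHUNT
) -> pd.DataFrame:
    """Add the two model transforms: ``sqrt_age`` and ``vs_spo2``.

    Raw columns are left intact. Requires imputation to have run first if
    the raw columns contain absent values (NaN propagates otherwise).
    """
    out = cohort.copy()
    age = out["age_months"].to_numpy(dtype=float)
    if np.any(age < 0):
        raise DomainError("age_months must be non-negative")
    out["sqrt_age"] = np.sqrt(age)
    out["vs_spo2"] = virtual_shunt(out["spo2_pct"].to_numpy(dtype=float), shunt)
    return out


@dataclass(frozen=True)
class EpvRule:
    """Events-per-variable screen: binary predictors need at least
    ``min_events`` outcome-positive carriers to stay in the candidate list."""

    min_events: int = 10

    def __post_init__(self):
        if self.min_events < 1:
            raise DomainError("EpvRule.min_events must be >= 1")


def epv_screen(
    cohort: pd.DataFrame,
    candidates: list[str],
    rule: EpvRule = EpvRule(),
    outcome_col: str = OUTCOME_COL,
) -> tuple[list[str], pd.DataFrame]:
    """Drop binary candidates with too few events among carriers.

    The event count for a binary predictor is the number of outcome-positive
    rows where the predictor equals 1. Continuous predictors have no defined
    per-level event count and are exempt from the screen.

    Returns the kept predictor list (original order) and an exclusion log
    with one row per candidate: ``predictor, binary, event_count, kept``.
    """
    y = cohort[outcome_col].to_numpy(dtype=float)
    rows = []
    kept: list[str] = []
    for name in candidates:
        col = cohort[name]
        binary = _is_categorical(col) and col.dtype != object
        if binary:
            events = int(np.nansum((col.to_numpy(dtype=float) == 1) & (y == 1)))
            keep = events >= rule.min_events
        else:
            events = int(np.nansum(y == 1))
            keep = True
        rows.append({"predictor": name, "binary": binary, "event_count": events, "kept": keep})
        if keep:
            kept.append(name)
    log = pd.DataFrame(rows)
    if not kept:
        warnings.warn("EPV screen removed every candidate predictor")
    return kept, log
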