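"""The published nine-predictor triage score as a fixed scoring function.

Applies the frozen published coefficients to one triage encounter: age in
months enters under a square root, SpO2 through the virtual-shunt transform,
and the resulting logit maps to an admission risk and a triage category at
the published 8%/40% thresholds. Nothing here re-estimates the constants.

Also houses the events-per-variable sample-size formula used to plan a
model-development cohort: ``N = (n_predictors * events_per_variable) /
event_rate``, rounded up.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DomainError
from .model import PUBLISHED_MODEL, PUBLISHED_THRESHOLDS
from .preprocess import transform_predictors
from .stratification import ThresholdPair, categorize

__all__ = ["triage_probability", "sample_size", "score_dataframe", "score_batch"]

_THRESHOLDS = ThresholdPair(*PUBLISHED_THRESHOLDS)

# (low, high, strict_low): heart rate and MUAC must be strictly positive
_RANGES = {
    "age_months": (0.0, None, False),
    "heart_rate_bpm": (0.0, None, True),
    "temperature_c": (33.0, 43.0, False),
    "muac_mm": (0.0, None, True),
    "spo2_pct": (0.0, 100.0, False),
}
_BINARIES = ("parent_concern", "difficulty_breathing", "oedema", "pallor")


def _validate_record(record: Mapping[str, float]) -> list[str]:
    bad = []
    for name, (lo, hi, strict) in _RANGES.items():
        v = record.get(name)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            bad.append(f"{name} absent")
            continue
        if v < lo or (strict and v == lo) or (hi is not None and v > hi):
            bad.append(f"{name}={v} out of range")
    for name in _BINARIES:
        v = record.get(name)
        if v not in (0, 1, 0.0, 1.0):
            bad.append(f"{name}={v} not in {{0,1}}")
    return bad


def triage_probability(record: Mapping[str, float]) -> tuple[float, str]:
    """Admission risk and triage category for one encounter.

    ``record`` must supply age_months, heart_rate_bpm, temperature_c,
    muac_mm, spo2_pct and the four binary signs. Probability is computed at
    full precision (report to 4 decimals); the category uses the published
    8%/40% boundaries at full precision.

    Raises
    ------
    DomainError
        Listing every absent or out-of-range field.
    """
    bad = _validate_record(record)
    if bad:
        raise DomainError("; ".join(bad))
    row = pd.DataFrame([{k: record[k] for k in list(_RANGES) + list(_BINARIES)}])
    p = float(PUBLISHED_MODEL.predict(transform_predictors(row))[0])
    return p, categorize(p, _THRESHOLDS)


def sample_size(
    n_predictors: int, event_rate: float, events_per_variable: int = 10
) -> int:
    """Minimum cohort size for a target events-per-variable ratio.

    ``ceil(n_predictors * events_per_variable / event_rate)``: e.g. 10
    expected predictors at a 20% event rate require 500 participants.
    """
    if n_predictors < 1 or events_per_variable < 1:
        raise DomainError("n_predictors and events_per_variable must be >= 1")
    if not (0 < event_rate <= 1):
        raise DomainError("event_rate must lie in (0, 1]")
    return math.ceil(n_predictors * events_per_variable / event_rate)


def score_dataframe(cohort: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every row of a cohort table with the published model.

    Returns ``(scored, errors)``: the scored table adds ``sqrt_age``,
    ``vs_spo2``, ``risk`` and ``triage_category`` columns for valid rows;
    invalid rows keep NaN scores and appear in the error report with their
    offending fields. Valid rows are always scored.
    """
    scored = cohort.copy()
    scored["sqrt_age"] = np.nan
    scored["vs_spo2"] = np.nan
    scored["risk"] = np.nan
    scored["triage_category"] = ""
    errors = []
    for i, (_, row) in enumerate(cohort.iterrows()):
        rec = row.to_dict()
        bad = _validate_record(rec)
        if bad:
            errors.append(
                {
                    "row": i,
                    "patient_id": rec.get("patient_id", ""),
                    "errors": "; ".join(bad),
                }
            )
            continue
        p, cat = triage_probability(rec)
        scored.iloc[i, scored.columns.get_loc("sqrt_age")] = math.sqrt(rec["age_months"])
        scored.iloc[i, scored.columns.get_loc("vs_spo2")] = (
            70.103 * math.log10(101.687 - rec["spo2_pct"]) - 55.833
        )
        scored.iloc[i, scored.columns.get_loc("risk")] = p
        scored.iloc[i, scored.columns.get_loc("triage_category")] = cat
    return scored, pd.DataFrame(errors, columns=["row", "patient_id", "errors"])


def score_batch(in_path, out_path, error_path=None) -> pd.DataFrame:
    """CSV-in, CSV-out batch scoring; per-row errors go to ``error_path``."""
    cohort = pd.read_csv(in_path)
    scored, errors = score_dataframe(cohort)
    scored.to_csv(out_path, index=False)
    if error_path is not None:
        errors.to_csv(error_path, index=False)
    return scored
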