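"""Logistic triage model container and the published nine-predictor model.

A :class:`TriageModel` is the interchange object of the whole pipeline: the
variable-selection stage produces one, the evaluation and stratification
stages consume one, and the fixed published model ships as a frozen instance.
Coefficients are keyed by *transformed* predictor column names (``sqrt_age``,
``vs_spo2``), i.e. the design matrix the model is meant to multiply is the
output of :func:`pedtriage.preprocess.transform_predictors`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TriageModel",
    "odds_ratio",
    "PUBLISHED_MODEL",
    "PUBLISHED_THRESHOLDS",
    "PUBLISHED_PREDICTORS",
]


def odds_ratio(coefficient: float) -> float:
    """Odds ratio for a one-unit increase in a predictor: ``exp(coefficient)``.

    Full precision is returned; round to two decimals for presentation.
    """
    return math.exp(coefficient)


@dataclass
class TriageModel:
    """A fitted (or fixed) logistic model for admission risk.

    Parameters
    ----------
    intercept : float
        Intercept on the logit scale.
    coefficients : mapping of predictor name to log-odds coefficient.
    standard_errors : optional mapping of predictor name to Wald SE.
    odds_ratio_ci : optional mapping of predictor name to
        ``(point, low, high)`` on the odds-ratio scale.
    n_obs, aic : fit metadata, ``None`` for a fixed model.
    notes : free-text fit log (e.g. a ridge fallback flag).
    """

    intercept: float
    coefficients: dict[str, float]
    standard_errors: dict[str, float] | None = None
    odds_ratio_ci: dict[str, tuple[float, float, float]] | None = None
    n_obs: int | None = None
    aic: float | None = None
    notes: str = ""

    @property
    def predictors(self) -> list[str]:
        return list(self.coefficients)

    def odds_ratios(self) -> dict[str, float]:
        """Point odds ratios, ``exp(beta)``, at full precision."""
        return {p: odds_ratio(b) for p, b in self.coefficients.items()}

    def linear_predictor(self, data: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        """Logit of the admission risk for each row of ``data``.

        ``data`` must already contain every predictor column named in
        :attr:`coefficients` (transformed columns included).
        """
        if isinstance(data, Mapping):
            data = pd.DataFrame([data])
        missing = [p for p in self.coefficients if p not in data.columns]
        if missing:
            raise KeyError(f"missing predictor columns: {missing}")
        eta = np.full(len(data), self.intercept, dtype=float)
        for name, beta in self.coefficients.items():
            eta += beta * data[name].to_numpy(dtype=float)
        return eta

    def predict(self, data: pd.DataFrame | Mapping[str, float]) -> np.ndarray:
        """Admission risk on the probability scale, strictly inside (0, 1)."""
        from scipy.special import expit

        # clip the logit so saturation cannot round to exactly 0 or 1
        return expit(np.clip(self.linear_predictor(data), -36.0, 36.0))

    # -- JSON interchange ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["odds_ratio_ci"] is not None:
            d["odds_ratio_ci"] = {k: list(v) for k, v in d["odds_ratio_ci"].items()}
        return d

    def to_json(self, path=None, **kwargs) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "TriageModel":
        d = dict(d)
        if d.get("odds_ratio_ci"):
            d["odds_ratio_ci"] = {k: tuple(v) for k, v in d["odds_ratio_ci"].items()}
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "TriageModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


#: Predictors of the published nine-predictor model, in reporting order.
PUBLISHED_PREDICTORS = [
    "sqrt_age",
    "heart_rate_bpm",
    "temperature_c",
    "muac_mm",
    "vs_spo2",
    "parent_concern",
    "difficulty_breathing",
    "oedema",
    "pallor",
]

#: The published pediatric triage model: admission risk from nine predictors.
#: Age enters in months under the square root; SpO2 enters through the
#: virtual-shunt transform (see :mod:`pedtriage.preprocess`). Constants are
#: fixed and must not be re-estimated.
PUBLISHED_MODEL = TriageModel(
    intercept=-32.888,
    coefficients={
        "sqrt_age": 0.252,
        "heart_rate_bpm": 0.016,
        "temperature_c": 0.819,
        "muac_mm": -0.022,
        "vs_spo2": 0.048,
        "parent_concern": 1.793,
        "difficulty_breathing": 1.012,
        "oedema": 1.814,
        "pallor": 1.506,
    },
    notes="published nine-predictor pediatric triage model (fixed constants)",
)

#: Published low/high risk thresholds: <=8% non-urgent, >40% emergency.
PUBLISHED_THRESHOLDS = (0.08, 0.40)
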