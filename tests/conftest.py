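import numpy as np
import pandas as pd
import pytest

from pedtriage import (
    GeneratorConfig,
    add_outcome,
    generate_cohort,
    impute,
    transform_predictors,
)


@pytest.fixture(scope="session")
def cohort_1612():
    """Default-sized synthetic cohort, raw (with missingness)."""
    return generate_cohort(GeneratorConfig(n_patients=1612, seed=7))


@pytest.fixture(scope="session")
def prepped_1612(cohort_1612):
    """Outcome derived, imputed, transformed."""
    return transform_predictors(impute(add_outcome(cohort_1612)))


@pytest.fixture(scope="session")
def prepped_5000():
    c = generate_cohort(GeneratorConfig(n_patients=5000, seed=19, missingness_rate=0.0))
    return transform_predictors(add_outcome(c))


def make_record(**overrides):
    """A plausible well-child triage record, overridable per test."""
    rec = {
        "age_months": 24.0,
        "heart_rate_bpm": 110.0,
        "temperature_c": 37.0,
        "muac_mm": 150.0,
        "spo2_pct": 98.0,
        "parent_concern": 0,
        "difficulty_breathing": 0,
        "oedema": 0,
        "pallor": 0,
    }
    rec.update(overrides)
    return rec
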