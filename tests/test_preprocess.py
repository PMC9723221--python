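import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pedtriage import (
    EpvRule,
    OutcomeRule,
    VirtualShuntParams,
    derive_outcome,
    epv_screen,
    impute,
    transform_predictors,
    virtual_shunt,
)
from pedtriage.errors import DataError, DomainError
from pedtriage.preprocess import OUTCOME_COL, add_outcome


def disposition(admitted, stay, readmit):
    return pd.DataFrame(
        {
            "admitted": [admitted],
            "length_of_stay_hours": [stay],
            "readmitted_within_48h": [readmit],
        }
    )


class TestVirtualShunt:
    @pytest.mark.parametrize(
        "spo2, expected",
        [(90, 19.02), (98, -16.11), (100, -39.91)],
    )
    def test_anchor_values(self, spo2, expected):
        # oracle: direct high-precision evaluation of the transform
        direct = 70.103 * math.log10(101.687 - spo2) - 55.833
        assert virtual_shunt(spo2) == pytest.approx(direct, abs=1e-12)
        assert virtual_shunt(spo2) == pytest.approx(expected, abs=0.01)

    @given(st.floats(min_value=0, max_value=99.99))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_decreasing(self, spo2):
        assert virtual_shunt(spo2) > virtual_shunt(spo2 + 0.01)

    @pytest.mark.parametrize("bad", [-1.0, 100.5, 101.0])
    def test_domain_error(self, bad):
        with pytest.raises(DomainError):
            virtual_shunt(bad)

    def test_vectorized(self):
        arr = np.array([90.0, 95.0, 100.0])
        out = virtual_shunt(arr)
        assert out.shape == (3,) and np.all(np.diff(out) < 0)

    def test_b_must_exceed_100(self):
        with pytest.raises(DomainError):
            VirtualShuntParams(b=99.0)


class TestOutcomeRule:
    @pytest.mark.parametrize(
        "admitted, stay, readmit, rule, expected",
        [
            (1, 36.0, 0, OutcomeRule(), 1),  # admitted long enough
            (0, np.nan, 1, OutcomeRule(), 1),  # early readmission
            (1, 12.0, 0, OutcomeRule(), 0),  # short stay
            (1, 12.0, 0, OutcomeRule(count_all_admissions=True), 1),
            (1, 24.0, 0, OutcomeRule(), 1),  # boundary: >= by default
            (1, 24.0, 0, OutcomeRule(strict_stay=True), 0),
            (0, np.nan, 0, OutcomeRule(), 0),
        ],
    )
    def test_rule(self, admitted, stay, readmit, rule, expected):
        assert derive_outcome(disposition(admitted, stay, readmit), rule)[0] == expected

    def test_admitted_without_stay_is_data_error(self):
        with pytest.raises(DataError):
            derive_outcome(disposition(1, np.nan, 0))

    def test_all_admissions_positive_set_is_superset(self, cohort_1612):
        default = derive_outcome(cohort_1612)
        robust = derive_outcome(cohort_1612, OutcomeRule(count_all_admissions=True))
        assert np.all(robust >= default)

    def test_invalid_rule_fields(self):
        with pytest.raises(DomainError):
            OutcomeRule(min_stay_hours=0)


class TestImpute:
    def test_continuous_median(self):
        df = pd.DataFrame({"muac_mm": [1.0, 2.0, np.nan, 100.0]})
        assert impute(df)["muac_mm"].iloc[2] == 2.0

    def test_binary_mode(self):
        df = pd.DataFrame({"pallor": [0.0, 0.0, 1.0, np.nan]})
        assert impute(df)["pallor"].iloc[3] == 0.0

    def test_mode_tie_breaks_to_smaller(self):
        df = pd.DataFrame({"pallor": [0.0, 1.0, np.nan]})
        assert impute(df)["pallor"].iloc[2] == 0.0

    def test_no_missing_is_identity(self):
        df = pd.DataFrame({"muac_mm": [1.0, 2.0, 3.0]})
        pd.testing.assert_frame_equal(impute(df), df)

    def test_idempotent(self, cohort_1612):
        once = impute(cohort_1612)
        pd.testing.assert_frame_equal(impute(once), once)

    def test_no_predictor_nan_left(self, cohort_1612):
        out = impute(cohort_1612)
        pred = out.drop(columns=["patient_id", "length_of_stay_hours"])
        assert not pred.isna().any().any()

    def test_disposition_never_imputed(self, cohort_1612):
        out = impute(cohort_1612)
        # non-admitted children keep an absent stay duration
        assert out.loc[out["admitted"] == 0, "length_of_stay_hours"].isna().all()

    def test_all_absent_column_errors(self):
        with pytest.raises(DataError, match="muac_mm"):
            impute(pd.DataFrame({"muac_mm": [np.nan, np.nan]}))


class TestTransforms:
    def test_sqrt_age(self):
        df = pd.DataFrame({"age_months": [144.0, 0.0], "spo2_pct": [98.0, 98.0]})
        out = transform_predictors(df)
        assert out["sqrt_age"].tolist() == [12.0, 0.0]
        assert out["vs_spo2"].iloc[0] == pytest.approx(-16.11, abs=0.01)

    def test_raw_columns_kept(self, cohort_1612):
        out = transform_predictors(impute(cohort_1612))
        assert {"age_months", "spo2_pct", "sqrt_age", "vs_spo2"} <= set(out.columns)

    def test_negative_age_errors(self):
        df = pd.DataFrame({"age_months": [-1.0], "spo2_pct": [98.0]})
        with pytest.raises(DomainError):
            transform_predictors(df)


class TestEpvScreen:
    def make(self, n_events_with_pred, n_pos=30, n=200):
        pred = np.zeros(n)
        y = np.zeros(n)
        y[:n_pos] = 1
        pred[:n_events_with_pred] = 1  # carriers among positives
        pred[n_pos : n_pos + 20] = 1  # carriers among negatives
        return pd.DataFrame({"flag": pred.astype(int), OUTCOME_COL: y.astype(int)})

    def test_below_threshold_dropped(self):
        kept, log = epv_screen(self.make(9), ["flag"])
        assert kept == [] and not log["kept"].iloc[0]
        assert log["event_count"].iloc[0] == 9

    def test_at_threshold_kept(self):
        kept, _ = epv_screen(self.make(10), ["flag"])
        assert kept == ["flag"]

    def test_zero_positive_outcomes_drop_all_binaries(self):
        df = self.make(0, n_pos=0)
        with pytest.warns(UserWarning):
            kept, _ = epv_screen(df, ["flag"])
        assert kept == []

    def test_continuous_exempt(self):
        df = pd.DataFrame(
            {"muac_mm": np.linspace(100, 200, 50), OUTCOME_COL: [1] * 5 + [0] * 45}
        )
        kept, log = epv_screen(df, ["muac_mm"])
        assert kept == ["muac_mm"] and not log["binary"].iloc[0]

    @pytest.mark.parametrize("lo, hi", [(1, 5), (5, 10), (10, 20)])
    def test_keep_list_monotone_in_min_events(self, prepped_1612, lo, hi):
        cands = ["parent_concern", "difficulty_breathing", "oedema", "pallor"]
        kept_lo, _ = epv_screen(prepped_1612, cands, EpvRule(lo))
        kept_hi, _ = epv_screen(prepped_1612, cands, EpvRule(hi))
        assert set(kept_hi) <= set(kept_lo)
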