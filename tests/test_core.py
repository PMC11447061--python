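"""Data model, classification, basal pooling, AUC and cohort I/O."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oralmm.core import (
    MGDL_PER_MMOLL,
    OgttSeries,
    RecordError,
    SchemaError,
    Subject,
    TOLERANCE_LABELS,
    basal_value,
    classify_tolerance,
    read_cohort,
    series_auc,
    tolerance_shares,
    trapezoid_auc,
    write_cohort,
)


class TestClassification:
    @pytest.mark.parametrize("g60,g120,label", [
        (8.5, 7.7, "NGT"),     # both just under the cut-offs
        (8.6, 7.7, "EGI"),     # isolated 1 h elevation
        (7.0, 11.1, "CFRD"),   # 2 h at the diabetes threshold
        (7.0, 7.8, "IGT"),     # 2 h at the lower IGT bound
        (12.0, 8.5, "IGT"),    # 2 h criterion dominates the 1 h value
        (12.0, 11.5, "CFRD"),
    ])
    def test_boundary_cases(self, g60, g120, label):
        assert classify_tolerance(g60, g120).label == label

    def test_ordinal_codes_ordered(self):
        codes = [classify_tolerance(*gg).ordinal_code
                 for gg in [(5.0, 5.0), (9.0, 7.0), (9.0, 9.0), (9.0, 12.0)]]
        assert codes == [0, 1, 2, 3]

    @given(st.floats(0.1, 25.0), st.floats(0.1, 25.0))
    @settings(max_examples=200, deadline=None)
    def test_partition(self, g60, g120):
        """Every point of the (1 h, 2 h) plane gets exactly one label."""
        status = classify_tolerance(g60, g120)
        assert status.label in TOLERANCE_LABELS

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            classify_tolerance(np.nan, 7.0)
        with pytest.raises(ValueError):
            classify_tolerance(8.0, -1.0)


class TestBasal:
    def test_mean_of_two_fasting_samples(self, tiny_series):
        tiny_series.glucose[:2] = [5.0, 5.2]
        assert basal_value(tiny_series, "glucose") == pytest.approx(5.1)

    def test_single_fasting_sample(self, tiny_series):
        tiny_series.glucose[0] = np.nan
        tiny_series.glucose[1] = 4.8
        assert basal_value(tiny_series, "glucose") == pytest.approx(4.8)

    def test_no_fasting_sample_errors(self, tiny_series):
        tiny_series.cpeptide[:2] = np.nan
        with pytest.raises(RecordError):
            basal_value(tiny_series, "cpeptide")


class TestTrapezoidAuc:
    def test_constant_profile_is_rectangle(self):
        assert trapezoid_auc([0, 60, 180], [5.0, 5.0, 5.0]) == pytest.approx(900.0)

    def test_linear_ramp_is_triangle(self):
        assert trapezoid_auc([0, 10], [0.0, 10.0]) == pytest.approx(50.0)

    def test_matches_fine_grid_integral_of_interpolant(self):
        t = np.array([0.0, 20.0, 60.0, 120.0, 180.0])
        v = np.array([5.0, 9.0, 10.0, 7.0, 5.5])  # concave-ish profile
        fine = np.linspace(0, 180, 360001)
        oracle = np.trapezoid(np.interp(fine, t, v), fine)
        assert trapezoid_auc(t, v) == pytest.approx(oracle, abs=1e-9)

    @given(st.floats(-2, 2), st.floats(-2, 2))
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, a, b):
        t = np.array([0.0, 15.0, 40.0, 90.0])
        x = np.array([1.0, 3.0, 2.0, 4.0])
        y = np.array([2.0, 1.0, 5.0, 3.0])
        lhs = trapezoid_auc(t, a * x + b * y)
        rhs = a * trapezoid_auc(t, x) + b * trapezoid_auc(t, y)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            trapezoid_auc([0.0], [1.0])

    def test_series_auc_anchors_at_zero(self, tiny_series):
        """The window starts at t=0 with the value interpolated between the
        -1 and 10 min draws."""
        auc = series_auc(tiny_series, "glucose")
        g0 = np.interp(0.0, tiny_series.times, tiny_series.glucose)
        grid = np.concatenate([[0.0], tiny_series.times[2:]])
        vals = np.concatenate([[g0], tiny_series.glucose[2:]])
        assert auc == pytest.approx(np.trapezoid(vals, grid), abs=1e-9)


class TestToleranceShares:
    def test_reported_shares_match_cohort_sizes(self):
        shares = tolerance_shares({"NGT": 13, "EGI": 20, "IGT": 10, "CFRD": 18})
        assert shares == {"NGT": 21, "EGI": 33, "IGT": 16, "CFRD": 30}

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError):
            tolerance_shares({})


class TestSeriesInvariants:
    def test_nonincreasing_times_rejected(self):
        with pytest.raises(RecordError, match="increasing"):
            OgttSeries("X", [-10, -1, 10, 10], [5] * 4, [40] * 4, [300] * 4)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(RecordError):
            OgttSeries("X", [-10, -1, 10], [5, 5, -1], [40] * 3, [300] * 3)

    def test_missing_fasting_sample_rejected(self):
        with pytest.raises(RecordError, match="fasting"):
            OgttSeries("X", [10, 20, 30], [5] * 3, [40] * 3, [300] * 3)

    def test_flags_report_missing_values(self, tiny_series):
        tiny_series.insulin[4] = np.nan
        assert any("missing insulin" in f for f in tiny_series.flags())

    def test_bmi_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            Subject("X", age=30, sex="male", height=180, weight=80, bmi=30.0)


class TestCohortIO:
    def _write_long(self, path, unit="mmol/l", glucose_value=5.5):
        rows = []
        times = [-10, -1, 10, 20, 30, 45, 60, 90, 120, 150, 180]
        for t in times:
            rows.append(("S1", t, "glucose", glucose_value))
            rows.append(("S1", t, "insulin", 50.0))
            rows.append(("S1", t, "cpeptide", 400.0))
        df = pd.DataFrame(rows, columns=["subject_id", "time", "analyte", "value"])
        df.to_csv(path, index=False)
        return df

    def test_long_identity_round_trip(self, tmp_path):
        p = tmp_path / "c.csv"
        self._write_long(p)
        records, report = read_cohort(p)
        assert report["n_read"] == 1 and not report["errors"]
        _, series = records[0]
        assert series.times.size == 11
        assert np.allclose(series.glucose, 5.5)

    def test_mgdl_conversion(self, tmp_path):
        p = tmp_path / "c.csv"
        self._write_long(p, glucose_value=99.0)
        records, _ = read_cohort(p, {"units": {"glucose": "mg/dl"}})
        _, series = records[0]
        # oracle: hand conversion of one row, 99 mg/dl / 18.016
        assert series.glucose[0] == pytest.approx(99.0 / 18.016)
        assert MGDL_PER_MMOLL == 18.016

    def test_duplicate_time_is_record_error(self, tmp_path):
        p = tmp_path / "c.csv"
        df = self._write_long(p)
        pd.concat([df, df.iloc[[0]]]).to_csv(p, index=False)
        _, report = read_cohort(p)
        assert "S1" in report["errors"]

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "c.csv"
        pd.DataFrame({"subject_id": ["S1"], "time": [0]}).to_csv(p, index=False)
        with pytest.raises(SchemaError, match="mandatory"):
            read_cohort(p)

    def test_write_read_round_trip(self, tmp_path, tiny_subject, tiny_series):
        p = tmp_path / "out.csv"
        write_cohort([(tiny_subject, tiny_series)], p)
        records, report = read_cohort(p, {"layout": "wide"})
        assert not report["errors"]
        subject, series = records[0]
        assert np.allclose(series.glucose, tiny_series.glucose, atol=1e-9)
        assert np.allclose(series.insulin, tiny_series.insulin, atol=1e-9)
        assert subject.sex == "female"
        assert subject.height == pytest.approx(165.0)
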