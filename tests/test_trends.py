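"""Per-month medians, median-on-age OLS, flatness labels, z-score outliers."""
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pfascohort import (
    AgeSeries,
    CohortTable,
    SerumMeasurement,
    build_age_series,
    classify_flatness,
    flag_outliers,
    group_median,
    group_stats,
    ols_fit,
    trend_table,
)

# Published per-month median rows and OLS coefficients (slope, intercept).
PUBLISHED_MEDIANS = {
    "PFOA": [2.65, 3.7, 3.3, 3.9, 3.8, 4.8, 3.75, 3.4, 3.55, 3.9, 4.3, 3.3],
    "PFOS": [8.1, 33.6, 19.5, 11, 11.1, 15.75, 8.95, 17.9, 13.1, 11.95, 14, 11.8],
    "PFNA": [0.984, 1.886, 1.968, 1.394, 0.82, 1.476, 0.984, 1.394, 1.066, 0.14, 0.984, 1.23],
    "PFHxS": [1.1, 1.7, 1.9, 1.5, 2, 2.15, 1.3, 1.9, 1.75, 2.15, 1.4, 1.4],
    "N-MeFOSAA": [0.35, 0.2, 0.3, 0.3, 0.2, 0.45, 0.25, 0.12, 0.21, 0.3, 0.3, 0.12],
    "PFDA": [0.17, 0.5, 0.7, 0.3, 0.14, 0.35, 0.25, 0.3, 0.25, 0.3, 0.2, 0.2],
}
PUBLISHED_FITS = {
    "PFOA": (0.04458, 3.450641),
    "PFOS": (-0.575, 17.89167),
    "PFNA": (-0.0651, 1.551872),
    "PFHxS": (0.008566, 1.640385),
    "N-MeFOSAA": (-0.00881, 0.306795),
    "PFDA": (-0.01762, 0.401923),
}


def _ols_oracle(x, y):
    """Normal-equations slope/intercept, independent of the fit path."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = ((x - x.mean()) ** 2).sum()
    sxy = ((x - x.mean()) * (y - y.mean())).sum()
    slope = sxy / sxx
    return slope, y.mean() - slope * x.mean()


class TestGroupMedian:
    def test_even_group_averages_middle_pair(self):
        # month-5 serum PFOS column
        assert group_median([29.8, 28.5, 18.5, 13, 8.7, 2.5]) == 15.75

    def test_singleton(self):
        assert group_median([7]) == 7

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="empty"):
            group_median([])

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=25),
           st.randoms(use_true_random=False))
    def test_permutation_invariant_and_bounded(self, values, rnd):
        med = group_median(values)
        assert min(values) <= med <= max(values)
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert group_median(shuffled) == med


class TestAgeSeries:
    def test_pfos_month1_median(self, nhanes):
        series = build_age_series(nhanes, "PFOS")
        assert series.medians[series.months.index(1)] == 33.6

    def test_pfna_month0_median(self, nhanes):
        series = build_age_series(nhanes, "PFNA")
        assert series.medians[series.months.index(0)] == 0.984

    @pytest.mark.parametrize("analyte", ["PFOS", "PFNA", "PFHxS", "N-MeFOSAA"])
    def test_uncorrupted_columns_reproduce_published_medians(self, nhanes, analyte):
        series = build_age_series(nhanes, analyte)
        assert list(series.medians) == pytest.approx(PUBLISHED_MEDIANS[analyte])

    def test_pfoa_medians_with_documented_override(self, nhanes, overrides):
        series = build_age_series(nhanes, "PFOA", overrides.get("PFOA"))
        assert list(series.medians) == pytest.approx(PUBLISHED_MEDIANS["PFOA"])

    def test_single_month_is_an_error(self, small_panel):
        records = [
            SerumMeasurement(f"s{i}", 4, "unknown", "PFOA", float(v))
            for i, v in enumerate([1, 2, 3])
        ]
        table = CohortTable(panel=small_panel, records=records)
        with pytest.raises(ValueError, match="2 distinct months"):
            build_age_series(table, "PFOA")

    def test_months_strictly_increasing_invariant(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            AgeSeries("X", months=(0, 0), medians=(1.0, 1.0), counts=(2, 2))


class TestOlsFit:
    @pytest.mark.parametrize("analyte,expected", PUBLISHED_FITS.items())
    def test_published_fits_at_printed_precision(self, nhanes, overrides, analyte, expected):
        series = build_age_series(nhanes, analyte, overrides.get(analyte))
        fit = ols_fit(series)
        slope, intercept = expected
        assert fit.slope == pytest.approx(slope, abs=10 ** (-_decimals(slope)) / 2)
        assert fit.intercept == pytest.approx(intercept, abs=10 ** (-_decimals(intercept)) / 2)

    def test_agrees_with_normal_equations_oracle(self, nhanes, overrides):
        for analyte in PUBLISHED_FITS:
            series = build_age_series(nhanes, analyte, overrides.get(analyte))
            fit = ols_fit(series)
            slope, intercept = _ols_oracle(series.months, series.medians)
            assert fit.slope == pytest.approx(slope, abs=1e-9)
            assert fit.intercept == pytest.approx(intercept, abs=1e-9)

    @given(
        st.floats(-5, 5, allow_nan=False),
        st.floats(-20, 20, allow_nan=False),
        st.integers(2, 12),
    )
    def test_exact_on_noiseless_line(self, a, b, n_months):
        months = tuple(range(n_months))
        series = AgeSeries(
            "X", months=months,
            medians=tuple(a * m + b for m in months),
            counts=(3,) * n_months,
        )
        fit = ols_fit(series)
        assert fit.slope == pytest.approx(a, abs=1e-8)
        assert fit.intercept == pytest.approx(b, abs=1e-8)

    def test_constant_series(self):
        series = AgeSeries("X", months=tuple(range(6)), medians=(2.5,) * 6, counts=(3,) * 6)
        fit = ols_fit(series)
        assert fit.slope == pytest.approx(0, abs=1e-12)
        assert fit.intercept == pytest.approx(2.5, abs=1e-12)


class TestFlatness:
    @pytest.mark.parametrize(
        "slope,label",
        [(0.04458, "flat"), (-0.0651, "flat"), (-0.575, "declining"),
         (0.1, "increasing"), (-0.1, "declining"), (0.3, "increasing")],
    )
    def test_labels(self, slope, label):
        from pfascohort import TrendFit

        fit = TrendFit("X", slope=slope, intercept=1.0, n_points=12)
        assert classify_flatness(fit, threshold=0.1) == label


class TestGroupStats:
    def test_pfos_month3_moments(self, nhanes):
        values = [r.value for r in nhanes.subset("PFOS") if r.age_months == 3]
        mean, sd = group_stats(values)
        assert round(mean) == 20
        assert round(sd) == 25
        assert mean == pytest.approx(20.25, abs=5e-3)
        assert sd == pytest.approx(25.29, abs=5e-3)

    @pytest.mark.parametrize(
        "values,expected",
        [([0, 0], (0, 0)), ([1, 3], (2, math.sqrt(2)))],
    )
    def test_small_cases(self, values, expected):
        mean, sd = group_stats(values)
        assert (mean, sd) == pytest.approx(expected)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_stats([5.0])


class TestOutliers:
    def test_pfos_extreme_month3_value_flagged(self, nhanes):
        reports = flag_outliers(nhanes, "PFOS", z_threshold=3.0)
        month3 = next(r for r in reports if r.age_months == 3)
        assert len(month3.flagged) == 1
        value, z = month3.flagged[0]
        assert value == 99.2
        assert z == pytest.approx(3.12, abs=5e-3)
        assert z > 3

    def test_pfoa_has_no_flags(self, nhanes):
        reports = flag_outliers(nhanes, "PFOA", z_threshold=3.0)
        assert all(not r.flagged for r in reports)

    def test_affine_invariance_of_flags(self, nhanes):
        base = flag_outliers(nhanes, "PFOS")
        scaled_records = [
            SerumMeasurement(r.subject_id, r.age_months, r.sex, r.analyte,
                             2.5 * r.value + 7.0, r.below_lod)
            for r in nhanes.subset("PFOS")
        ]
        scaled = CohortTable(panel=nhanes.panel, records=scaled_records)
        rescaled = flag_outliers(scaled, "PFOS")
        for b, s in zip(base, rescaled):
            assert [z for _, z in b.flagged] == pytest.approx(
                [z for _, z in s.flagged], abs=1e-9
            )

    def test_removing_flagged_value_shrinks_sd(self, nhanes):
        month3 = [r.value for r in nhanes.subset("PFOS") if r.age_months == 3]
        _, sd_all = group_stats(month3)
        _, sd_trimmed = group_stats([v for v in month3 if v != 99.2])
        assert sd_trimmed < sd_all

    def test_small_groups_skipped_not_failed(self, small_panel, caplog):
        records = [
            SerumMeasurement("a", 0, "unknown", "PFOA", 1.0),
            SerumMeasurement("b", 0, "unknown", "PFOA", 2.0),
            SerumMeasurement("c", 1, "unknown", "PFOA", 1.0),
            SerumMeasurement("d", 1, "unknown", "PFOA", 2.0),
            SerumMeasurement("e", 1, "unknown", "PFOA", 3.0),
        ]
        table = CohortTable(panel=small_panel, records=records)
        import logging

        with caplog.at_level(logging.INFO, logger="pfascohort.trends"):
            reports = flag_outliers(table, "PFOA", min_group=3)
        assert [r.age_months for r in reports] == [1]
        assert any("skipped" in rec.message for rec in caplog.records)

    def test_pooled_scope_single_group(self, nhanes):
        reports = flag_outliers(nhanes, "PFOS", scope="pooled")
        assert len(reports) == 1


class TestTrendTable:
    def test_reproduces_published_summary(self, nhanes, overrides):
        tt = trend_table(
            nhanes, ["PFDA", "PFOA", "PFOS", "PFHxS", "N-MeFOSAA"],
            median_overrides=overrides,
        )
        for analyte, (slope, intercept) in PUBLISHED_FITS.items():
            if analyte == "PFNA":
                continue
            assert tt.loc["slope", analyte] == pytest.approx(slope, abs=1e-5)
            assert tt.loc["intercept", analyte] == pytest.approx(intercept, abs=1e-5)

    def test_single_analyte_layout(self, nhanes):
        tt = trend_table(nhanes, ["PFOS"])
        assert list(tt.columns) == ["PFOS"]
        assert "median_m0" in tt.index and "slope" in tt.index


def _decimals(x: float) -> int:
    """Number of decimal places in a published value (for half-ulp tolerance)."""
    text = repr(x)
    return len(text.split(".")[1]) if "." in text else 0
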