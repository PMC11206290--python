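"""Retention transform, replicate aggregation, and R_M0 extrapolation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromlip import (
    RetentionMeasurement,
    RetentionSeries,
    aggregate_replicates,
    compute_c0,
    fit_retention,
    rf_to_rm,
    rm_to_rf,
)
from chromlip.errors import (
    InsufficientDesignError,
    UndefinedValueError,
    ValidationError,
)
from chromlip.rounding import round_half_up
from conftest import ols_oracle


class TestRfToRm:
    @pytest.mark.parametrize(
        "rf, expected",
        [(0.5, 0.0), (0.1, 0.95424), (0.9, -0.95424)],
    )
    def test_known_values(self, rf, expected):
        assert rf_to_rm(rf) == pytest.approx(expected, abs=5e-6)

    @pytest.mark.parametrize("rf", [0.0, 1.0, -0.1, 1.5])
    def test_domain_error(self, rf):
        with pytest.raises(UndefinedValueError):
            rf_to_rm(rf)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(max_examples=200, derandomize=True)
    def test_antisymmetric_about_half(self, rf):
        assert rf_to_rm(rf) + rf_to_rm(1.0 - rf) == pytest.approx(0.0, abs=1e-9)

    @given(st.floats(min_value=-5, max_value=5))
    @settings(max_examples=100, derandomize=True)
    def test_inverse_round_trip(self, rm):
        assert rf_to_rm(rm_to_rf(rm)) == pytest.approx(rm, abs=1e-9)

    def test_strictly_decreasing(self):
        grid = np.linspace(0.01, 0.99, 50)
        assert np.all(np.diff(rf_to_rm(grid)) < 0)


class TestAggregateReplicates:
    def test_symmetric_replicates_average_to_zero_rm(self):
        ms = [RetentionMeasurement(1, 0.5, rf, rep + 1)
              for rep, rf in enumerate([0.4, 0.5, 0.6])]
        (series,) = aggregate_replicates(ms)
        assert series.rm == pytest.approx((0.0,), abs=1e-12)

    def test_single_replicate_is_pass_through(self):
        ms = [RetentionMeasurement(1, c, rf)
              for c, rf in [(0.5, 0.3), (0.6, 0.45), (0.7, 0.6)]]
        (series,) = aggregate_replicates(ms)
        assert series.rm == pytest.approx(tuple(rf_to_rm(rf) for rf in (0.3, 0.45, 0.6)))

    def test_rf_and_rm_scale_orders_differ_on_asymmetric_replicates(self):
        # brute force both orders for replicates {0.2, 0.6} at one level
        ms = [RetentionMeasurement(1, 0.5, 0.2, 1), RetentionMeasurement(1, 0.5, 0.6, 2)]
        (on_rf,) = aggregate_replicates(ms, scale="rf")
        (on_rm,) = aggregate_replicates(ms, scale="rm")
        assert on_rf.rm[0] == pytest.approx(rf_to_rm(0.4))
        assert on_rm.rm[0] == pytest.approx((rf_to_rm(0.2) + rf_to_rm(0.6)) / 2)
        assert on_rf.rm[0] != pytest.approx(on_rm.rm[0], abs=1e-3)

    def test_compounds_kept_separate(self):
        ms = [RetentionMeasurement(cid, 0.5, 0.4) for cid in (1, 2, 3)]
        assert [s.compound_id for s in aggregate_replicates(ms)] == [1, 2, 3]


class TestFitRetention:
    @staticmethod
    def _noiseless(rm0, b, c_values):
        c = tuple(c_values)
        return RetentionSeries(1, c, tuple(rm0 + b * ci for ci in c))

    def test_exact_line_recovered_with_tabulated_c0(self):
        series = self._noiseless(3.45, -4.77, np.arange(0.50, 0.801, 0.05))
        fit = fit_retention(series)
        assert fit.rm0 == pytest.approx(3.45, abs=1e-12)
        assert fit.b == pytest.approx(-4.77, abs=1e-12)
        assert fit.r_abs == pytest.approx(1.0, abs=1e-12)
        assert round_half_up(fit.c0, 4) == 0.7233

    def test_noiseless_recovery_machine_precision(self):
        fit = fit_retention(self._noiseless(2.0, -3.0, [0.5, 0.6, 0.7]))
        assert fit.rm0 == pytest.approx(2.0, abs=1e-13)
        assert fit.b == pytest.approx(-3.0, abs=1e-13)

    def test_matches_normal_equation_oracle_with_noise(self):
        rng = np.random.default_rng(42)
        c = np.arange(0.50, 0.801, 0.05)
        rm = 3.5 - 4.8 * c + rng.normal(0, 0.05, size=c.size)
        fit = fit_retention(RetentionSeries(1, tuple(c), tuple(rm)))
        slope, intercept, r = ols_oracle(c, rm)
        assert fit.b == pytest.approx(slope, abs=1e-10)
        assert fit.rm0 == pytest.approx(intercept, abs=1e-10)
        assert fit.r_abs == pytest.approx(abs(r), abs=1e-10)

    def test_too_few_levels(self):
        with pytest.raises(InsufficientDesignError):
            fit_retention(RetentionSeries(1, (0.5, 0.6), (1.0, 0.5)))

    def test_flat_series_has_undefined_c0(self):
        fit = fit_retention(RetentionSeries(1, (0.5, 0.6, 0.7), (1.0, 1.0, 1.0)))
        assert fit.b == 0.0
        assert fit.c0 is None


class TestComputeC0:
    @pytest.mark.parametrize(
        "rm0, b, expected",
        [(3.45, -4.77, 0.7233), (3.23, -4.21, 0.7672)],
    )
    def test_tabulated_values(self, rm0, b, expected):
        assert round_half_up(compute_c0(rm0, b), 4) == expected

    @given(st.floats(min_value=0.1, max_value=100))
    @settings(max_examples=50, derandomize=True)
    def test_symmetry(self, x):
        assert compute_c0(x, -x) == pytest.approx(1.0)

    def test_zero_slope(self):
        with pytest.raises(UndefinedValueError):
            compute_c0(1.0, 0.0)


class TestValidation:
    @pytest.mark.parametrize("rf", [0.0, 1.0, 1.2, -0.5])
    def test_measurement_rejects_rf_outside_open_interval(self, rf):
        with pytest.raises(ValidationError):
            RetentionMeasurement(1, 0.5, rf)

    def test_series_requires_increasing_c(self):
        with pytest.raises(ValidationError):
            RetentionSeries(1, (0.5, 0.5, 0.6), (1.0, 1.0, 0.5))

    def test_ols_property_against_oracle(self):
        """OLS agrees with the normal-equation oracle on 100 random instances."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(3, 12)
            c = np.sort(rng.uniform(0, 0.95, size=n))
            while np.ptp(c) == 0 or len(set(c)) < 3:
                c = np.sort(rng.uniform(0, 0.95, size=n))
            rm = rng.normal(2, 1) + rng.normal(-4, 1) * c + rng.normal(0, 0.1, n)
            c = np.unique(c)
            rm = rm[: len(c)]
            if len(c) < 3:
                continue
            fit = fit_retention(RetentionSeries(1, tuple(c), tuple(rm)))
            slope, intercept, r = ols_oracle(c, rm)
            assert fit.b == pytest.approx(slope, abs=1e-10)
            assert fit.rm0 == pytest.approx(intercept, abs=1e-10)
            assert fit.r_abs == pytest.approx(abs(r), abs=1e-10)
            assert math.copysign(1, fit.r_signed) == math.copysign(1, r)
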