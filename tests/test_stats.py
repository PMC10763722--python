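"""Normality-gated comparisons, length regressions, slope-equality tests."""

import numpy as np
import pytest

from titinsted.profiler import SarcomereMeasurement
from titinsted.stats import (
    RegressionResult,
    StatsError,
    compare_groups,
    compare_slopes,
    fit_length_regression,
)


def measurement(sl_um, value, qc=True):
    return SarcomereMeasurement(
        sl_nm=sl_um * 1000.0,
        aband_titin_len_nm=value,
        m_position_nm=0.0,
        dtk_nm=value,
        a170_separation_nm=2 * value,
        mir_fwhm_nm=50.0,
        a170_fwhm_nm=50.0,
        a170_over_mir_intensity=1.0,
        qc_pass=qc,
        qc_reasons=() if qc else ("MIR",),
    )


def regression_from_arrays(sl, y, metric="aband_titin_len_nm", group=""):
    return fit_length_regression(
        [measurement(s, v) for s, v in zip(sl, y)], metric,
        sl_range_um=(min(sl), max(sl)), group=group,
    )


class TestCompareGroups:
    def test_identical_groups_statistic_zero(self):
        vals = list(np.random.default_rng(0).normal(0, 1, 30))
        res = compare_groups({"a": vals, "b": vals})
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.method in ("t", "welch_t")

    def test_separated_normals_significant(self):
        rng = np.random.default_rng(1)
        res = compare_groups({"a": rng.normal(0, 1, 200), "b": rng.normal(1, 1, 200)})
        assert res.method in ("t", "welch_t")
        assert res.p_value < 1e-6  # power ~ 1 at this separation

    def test_skewed_group_gates_to_mann_whitney(self):
        rng = np.random.default_rng(2)
        res = compare_groups({"a": rng.lognormal(0, 1.5, 80), "b": rng.normal(0, 1, 80)})
        assert res.method == "mann_whitney"

    def test_unequal_variances_gate_to_welch(self):
        rng = np.random.default_rng(3)
        res = compare_groups({"a": rng.normal(0, 1, 100), "b": rng.normal(0, 5, 100)})
        assert res.method == "welch_t"
        assert res.variance_equality_p < 0.05

    def test_three_normal_groups_anova(self):
        rng = np.random.default_rng(4)
        res = compare_groups({g: rng.normal(0, 1, 40) for g in "abc"})
        assert res.method == "anova"

    def test_three_groups_with_skew_kruskal(self):
        rng = np.random.default_rng(5)
        samples = {"a": rng.normal(0, 1, 40), "b": rng.normal(0, 1, 40),
                   "c": rng.lognormal(0, 1.5, 40)}
        assert compare_groups(samples).method == "kruskal"

    def test_small_group_rejected(self):
        with pytest.raises(StatsError, match="n = 2"):
            compare_groups({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


class TestLengthRegression:
    def test_collinear_points_recover_slope_exactly(self):
        sl = np.linspace(1.8, 2.6, 20)
        y = 0.236 * sl + 3.0
        reg = regression_from_arrays(sl, y)
        assert reg.slope == pytest.approx(0.236, abs=1e-12)
        assert reg.se_slope == pytest.approx(0.0, abs=1e-9)

    def test_constant_metric_zero_slope(self):
        sl = np.linspace(1.8, 2.6, 10)
        reg = regression_from_arrays(sl, np.full(10, 7.0))
        assert reg.slope == pytest.approx(0.0, abs=1e-12)
        assert reg.se_slope == pytest.approx(0.0, abs=1e-9)

    def test_ols_matches_normal_equations(self):
        rng = np.random.default_rng(6)
        sl = rng.uniform(1.8, 2.6, 60)
        y = 100 + 30 * sl + rng.normal(0, 5, 60)
        reg = regression_from_arrays(sl, y)
        # closed-form normal equations as the independent oracle
        X = np.column_stack([np.ones_like(sl), sl])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert reg.intercept == pytest.approx(beta[0], rel=1e-9)
        assert reg.slope == pytest.approx(beta[1], rel=1e-9)
        resid = y - X @ beta
        s2 = resid @ resid / (60 - 2)
        cov = s2 * np.linalg.inv(X.T @ X)
        assert reg.se_slope == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-9)

    def test_out_of_window_points_ignored(self):
        sl = np.linspace(1.8, 2.6, 20)
        y = 200 * sl + 1000
        ms = [measurement(s, v) for s, v in zip(sl, y)]
        ms += [measurement(2.9, 0.0), measurement(1.65, 9999.0)]
        reg = fit_length_regression(ms, "aband_titin_len_nm", (1.8, 2.6))
        assert reg.slope == pytest.approx(200.0, abs=1e-9)
        assert reg.n_excluded_range == 2

    def test_qc_failed_points_excluded_and_counted(self):
        sl = np.linspace(1.8, 2.6, 10)
        ms = [measurement(s, 100.0) for s in sl] + [measurement(2.0, 1e6, qc=False)]
        reg = fit_length_regression(ms, "aband_titin_len_nm")
        assert reg.n_excluded_qc == 1
        assert reg.slope == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_points_rejected(self):
        with pytest.raises(StatsError, match="insufficient"):
            fit_length_regression([measurement(2.0, 1.0)] * 2, "dtk_nm")


class TestCompareSlopes:
    def test_identical_datasets_delta_zero(self):
        rng = np.random.default_rng(7)
        sl = rng.uniform(1.8, 2.6, 50)
        y = 100 + 30 * sl + rng.normal(0, 5, 50)
        a = regression_from_arrays(sl, y, group="a")
        b = regression_from_arrays(sl, y, group="b")
        res = compare_slopes(a, b)
        assert res.delta_slope == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_different_generative_slopes_detected(self):
        rng = np.random.default_rng(8)
        sl = np.repeat([1.8, 2.0, 2.2, 2.4, 2.6], 50)
        ya = 1400 + 236 * (sl - 1.8) + rng.normal(0, 10, sl.size)
        yb = 1400 + 150 * (sl - 1.8) + rng.normal(0, 10, sl.size)
        res = compare_slopes(regression_from_arrays(sl, ya, group="neg"),
                             regression_from_arrays(sl, yb, group="pos"))
        assert res.delta_slope == pytest.approx(-86.0, abs=15.0)
        assert res.p_value < 0.05

    def test_metric_mismatch_rejected(self):
        rng = np.random.default_rng(9)
        sl = rng.uniform(1.8, 2.6, 20)
        a = regression_from_arrays(sl, sl * 10, metric="dtk_nm")
        b = regression_from_arrays(sl, sl * 10, metric="aband_titin_len_nm")
        with pytest.raises(StatsError, match="mismatch"):
            compare_slopes(a, b)

    def test_type_i_error_near_nominal(self):
        """Monte-Carlo calibration: on identical generative parameters the
        slope-equality test rejects at ~ the nominal 5% level."""
        rng = np.random.default_rng(10)
        n_rep, n = 400, 30
        rejections = 0
        for _ in range(n_rep):
            sl = np.repeat([1.8, 2.2, 2.6], n // 3)
            ya = 10 * sl + rng.normal(0, 2, n)
            yb = 10 * sl + rng.normal(0, 2, n)
            res = compare_slopes(regression_from_arrays(sl, ya, group="a"),
                                 regression_from_arrays(sl, yb, group="b"))
            rejections += res.p_value < 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) < 2.5 * se
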