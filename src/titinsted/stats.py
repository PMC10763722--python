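"""Normality-gated group comparisons and sarcomere-length regressions.

The comparison policy follows common practice in muscle biophysics: check
each group with Shapiro-Wilk; for two normal groups use Student's t
(Welch-corrected when a Levene test rejects equal variances), otherwise
Mann-Whitney U; for three or more groups use one-way ANOVA when all are
normal, otherwise Kruskal-Wallis.  Length dependence of per-sarcomere
metrics is fitted by ordinary least squares over a sarcomere-length
window, and slopes of two groups are compared with a pooled
dummy-coded interaction model.  No multiple-testing correction is
applied; reports flag this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sstats

from .geometry import SLACK_SL_UM
from .profiler import SarcomereMeasurement

logger = logging.getLogger(__name__)


class StatsError(ValueError):
    """Raised for insufficient data or mismatched comparison requests."""


@dataclass(frozen=True)
class GroupComparison:
    groups: tuple[str, ...]
    method: str  # t, welch_t, mann_whitney, anova, kruskal
    statistic: float
    p_value: float
    normality_p: dict[str, float] = field(default_factory=dict)
    variance_equality_p: float | None = None

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "normality_p": dict(self.normality_p),
            "variance_equality_p": self.variance_equality_p,
            "multiple_testing_correction": "none",
        }


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of one per-sarcomere metric against sarcomere length (µm)."""

    metric: str
    group: str
    slope: float
    intercept: float
    intercept_at_slack: float
    se_slope: float
    se_intercept: float
    n: int
    sl_range_um: tuple[float, float]
    n_excluded_qc: int = 0
    n_excluded_range: int = 0
    # raw in-window points, retained so two fits can be pooled for a
    # slope-equality test without refitting from measurements
    sl_um: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)
    y: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)

    def predict(self, sl_um: float) -> float:
        return self.intercept + self.slope * sl_um


def compare_groups(samples: Mapping[str, Sequence[float]], alpha: float = 0.05) -> GroupComparison:
    """Normality-gated comparison of two or more groups."""
    names = tuple(samples.keys())
    arrays = [np.asarray(samples[g], dtype=float) for g in names]
    if len(names) < 2:
        raise StatsError("need >= 2 groups")
    for g, arr in zip(names, arrays):
        if arr.size < 3:
            raise StatsError(f"group {g!r} has n = {arr.size} < 3")
    normality = {}
    for g, arr in zip(names, arrays):
        if np.ptp(arr) == 0:
            normality[g] = 1.0  # constant data: treat as compatible with normality
        else:
            normality[g] = float(sstats.shapiro(arr).pvalue)
    all_normal = all(p >= alpha for p in normality.values())

    if len(names) == 2:
        a, b = arrays
        if all_normal:
            lev_p = float(sstats.levene(a, b).pvalue)
            equal_var = lev_p >= alpha
            res = sstats.ttest_ind(a, b, equal_var=equal_var)
            method = "t" if equal_var else "welch_t"
            stat, p = float(res.statistic), float(res.pvalue)
            if np.isnan(stat):  # zero variance in both groups
                stat = 0.0
                p = 1.0 if np.mean(a) == np.mean(b) else 0.0
        else:
            lev_p = None
            res = sstats.mannwhitneyu(a, b, alternative="two-sided")
            method = "mann_whitney"
            stat, p = float(res.statistic), float(res.pvalue)
        return GroupComparison(names, method, stat, p, normality, lev_p)

    if all_normal:
        res = sstats.f_oneway(*arrays)
        method = "anova"
    else:
        res = sstats.kruskal(*arrays)
        method = "kruskal"
    return GroupComparison(names, method, float(res.statistic), float(res.pvalue), normality, None)


#: mapping from public metric names to SarcomereMeasurement attributes
METRIC_ATTRS = {
    "aband_titin_len_nm": "aband_titin_len_nm",
    "dtk_nm": "dtk_nm",
    "a170_separation_nm": "a170_separation_nm",
    "mir_fwhm_nm": "mir_fwhm_nm",
    "a170_fwhm_nm": "a170_fwhm_nm",
    "a170_over_mir_intensity": "a170_over_mir_intensity",
    "mir_fwhm_over_height": "mir_fwhm_over_height",
}


def fit_length_regression(
    measurements: Sequence[SarcomereMeasurement],
    metric: str,
    sl_range_um: tuple[float, float] = (1.8, 2.6),
    group: str = "",
    require_qc: bool = True,
) -> RegressionResult:
    """OLS of a per-sarcomere metric on sarcomere length within a window.

    QC-failed measurements are excluded (and counted), as are points whose
    SL falls outside ``sl_range_um``.
    """
    if metric not in METRIC_ATTRS:
        raise StatsError(f"unknown metric {metric!r}; choose from {sorted(METRIC_ATTRS)}")
    attr = METRIC_ATTRS[metric]
    sl: list[float] = []
    y: list[float] = []
    n_qc = 0
    n_range = 0
    lo, hi = sl_range_um
    for m in measurements:
        if require_qc and not m.qc_pass:
            n_qc += 1
            continue
        sl_um = m.sl_nm / 1000.0
        value = getattr(m, attr)
        if value is None:
            continue
        if not lo <= sl_um <= hi:
            n_range += 1
            continue
        sl.append(sl_um)
        y.append(float(value))
    if len(sl) < 3:
        raise StatsError(
            f"insufficient data: {len(sl)} in-range QC-passed points "
            f"({n_qc} QC-excluded, {n_range} out of range)"
        )
    sl_arr = np.asarray(sl)
    y_arr = np.asarray(y)
    X = sm.add_constant(sl_arr)
    fit = sm.OLS(y_arr, X).fit()
    intercept, slope = fit.params
    se_int, se_slope = fit.bse
    logger.info("regression %s/%s: slope %.3f ± %.3f (n=%d, %d QC-excluded, %d out-of-range)",
                group or "-", metric, slope, se_slope, len(sl), n_qc, n_range)
    return RegressionResult(
        metric=metric,
        group=group,
        slope=float(slope),
        intercept=float(intercept),
        intercept_at_slack=float(intercept + slope * SLACK_SL_UM),
        se_slope=float(se_slope),
        se_intercept=float(se_int),
        n=len(sl),
        sl_range_um=sl_range_um,
        n_excluded_qc=n_qc,
        n_excluded_range=n_range,
        sl_um=sl_arr,
        y=y_arr,
    )


@dataclass(frozen=True)
class SlopeComparison:
    delta_slope: float
    p_value: float
    delta_intercept_at_slack: float
    p_intercept: float
    n: int


def compare_slopes(a: RegressionResult, b: RegressionResult) -> SlopeComparison:
    """Slope-equality test between two length regressions of the same metric.

    Refits the pooled model ``y ~ sl + group + group:sl`` (group dummy =
    1 for ``b``); the interaction coefficient is the slope difference and
    its t-test the reported p-value.  The intercept difference is
    evaluated at the slack length of 1.8 µm (SL centred at slack before
    fitting so the group main effect is the offset there).
    """
    if a.metric != b.metric:
        raise StatsError(f"metric mismatch: {a.metric!r} vs {b.metric!r}")
    if a.sl_um.size == 0 or b.sl_um.size == 0:
        raise StatsError("RegressionResult objects lack retained data points")
    sl = np.concatenate([a.sl_um, b.sl_um]) - SLACK_SL_UM
    y = np.concatenate([a.y, b.y])
    g = np.concatenate([np.zeros(a.sl_um.size), np.ones(b.sl_um.size)])
    X = sm.add_constant(np.column_stack([sl, g, g * sl]))
    fit = sm.OLS(y, X).fit()
    # columns: const, sl, group, group:sl
    return SlopeComparison(
        delta_slope=float(fit.params[3]),
        p_value=float(fit.pvalues[3]),
        delta_intercept_at_slack=float(fit.params[2]),
        p_intercept=float(fit.pvalues[2]),
        n=int(y.size),
    )
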