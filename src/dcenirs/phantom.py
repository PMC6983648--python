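"""Phantom validation: measured vs expected absorption changes.

The system check regresses measured absorption changes against the expected
values from the ink titration with the intercept fixed at zero (no ink, no
absorption change).  For the no-intercept model the slope is
sum(x y) / sum(x^2), R^2 is computed about the origin, and the F test has
(1, n-1) degrees of freedom.  Residual normality is screened with the
Shapiro-Wilk test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dtof import InputError
from .perfusion import quantify_stack  # noqa: F401  (re-exported convenience)


@dataclass
class RegressionResult:
    slope: float
    r_squared: float
    f_stat: float
    df: tuple  # (1, n-1)
    p_value: float
    residuals: np.ndarray
    shapiro_p: float
    expected: np.ndarray
    measured: np.ndarray


def regress_through_origin(expected, measured) -> RegressionResult:
    """Zero-intercept least squares of measured on expected absorption changes."""
    x = np.asarray(expected, dtype=float)
    y = np.asarray(measured, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("expected and measured must be 1-D arrays of equal length")
    if x.size < 3:
        raise InputError("need at least 3 points for the zero-intercept regression")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise InputError("expected values are degenerate (all zero)")
    slope = float(np.sum(x * y) / sxx)
    fitted = slope * x
    resid = y - fitted
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum(y**2))  # uncentered: the model is forced through 0
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    df2 = x.size - 1
    if ss_res == 0:
        f = np.inf
        p = 0.0
    else:
        f = (slope**2 * sxx) / (ss_res / df2)
        p = float(stats.f.sf(f, 1, df2))
    if np.ptp(resid) == 0:
        shapiro_p = np.nan  # constant residuals: normality test undefined
    else:
        shapiro_p = float(stats.shapiro(resid).pvalue)
    return RegressionResult(slope, r2, float(f), (1, df2), p, resid, shapiro_p, x, y)


def measure_phantom_steps(series) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-step measured absorption change (mean, SD over frames) of a titration.

    The Beer-Lambert conversion is applied per frame against the ink-free
    baseline set (its mean intensity and its pathlength), then averaged within
    each step.  Returns (expected, measured_mean, measured_sd) and fills the
    measured fields of the series' steps in place.
    """
    from .dtof import DTOF, mean_time_of_flight
    from .constants import C_VACUUM_CM_PER_NS

    base = series.baseline_stack
    i0 = float(base.counts.sum(axis=1).mean())
    base_mean = DTOF(base.counts.mean(axis=0), base.bin_width_ns, base.t_start_ns)
    p = (
        C_VACUUM_CM_PER_NS
        / series.scene.n_tissue
        * (mean_time_of_flight(base_mean) - mean_time_of_flight(series.irf))
    )
    expected, meas, sd = [], [], []
    for step, stack in zip(series.steps, series.step_stacks):
        per_frame = np.log(i0 / stack.counts.sum(axis=1)) / p
        step.measured_delta_mua = float(per_frame.mean())
        step.measured_sd = float(per_frame.std(ddof=1))
        expected.append(step.expected_delta_mua)
        meas.append(step.measured_delta_mua)
        sd.append(step.measured_sd)
    return np.asarray(expected), np.asarray(meas), np.asarray(sd)


def phantom_pipeline(series) -> RegressionResult:
    """Measured-vs-expected zero-intercept regression for a full titration series."""
    if len(series.steps) < 3:
        raise InputError("phantom validation needs at least 3 titration steps")
    expected, measured, _ = measure_phantom_steps(series)
    return regress_through_origin(expected, measured)
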