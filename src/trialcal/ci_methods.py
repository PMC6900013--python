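"""Confidence intervals for the measurement-error-corrected treatment effect.

The corrected effect is a ratio of independent estimates (trial slope over
calibration slope), so four constructions are offered:

* **zero-variance** — the calibration parameters are treated as known
  constants; only the trial-fit variance is propagated.  Anti-conservative
  by construction (it ignores calibration uncertainty) but a useful floor.
* **delta** — first-order Taylor variance of the ratio, exploiting the
  independence of the trial sample and the external calibration sample.
* **Fieller** — exact inversion of the pivotal quantity for a ratio of
  normal estimates.  The interval is bounded only when the calibration
  slope is significantly non-zero at the working t-quantile; otherwise the
  confidence set is unbounded and the result is flagged ``defined=False``
  (a legal outcome that the simulation engine counts, not an exception).
* **percentile bootstrap** — within-arm resampling of the trial and
  independent resampling of the calibration sample, re-estimating the
  corrected effect on each resample.  Resamples with a degenerate
  calibration (constant error-free endpoint, or exactly zero slope) are
  dropped and the effective number of resamples reported.

Zero-variance and delta intervals use the t distribution with N - 2 degrees
of freedom (the trial fit dominates); the same quantile enters the Fieller
quadratic.  For the differential structure the trial variance is the HC3
sandwich (the per-arm residual variances differ by construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Tuple, Union

import numpy as np
from scipy import stats

from .datagen import CalibrationDataset, TrialDataset
from .errors import BootstrapFailureError, DataValidationError
from .estimators import (
    CalibrationFit,
    CorrectedEstimate,
    NaiveFit,
)

__all__ = [
    "IntervalResult",
    "naive_wald_interval",
    "ci_zero_variance",
    "ci_delta",
    "ci_fieller",
    "ci_bootstrap",
]


@dataclass
class IntervalResult:
    """A two-sided confidence interval with a definedness flag."""

    lower: float
    upper: float
    defined: bool
    method: str
    alpha_level: float
    effective_b: Optional[int] = None  # bootstrap only

    def contains(self, value: float) -> bool:
        return bool(self.defined and self.lower <= value <= self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower if self.defined else math.nan


@lru_cache(maxsize=None)
def _tcrit(df: int, alpha: float) -> float:
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def naive_wald_interval(fit: NaiveFit, alpha: float = 0.05, robust: bool = False) -> IntervalResult:
    """Wald interval for the naive slope (model-based or HC3 variance)."""
    vcov = fit.robust_vcov if robust else fit.vcov
    if vcov is None:
        raise DataValidationError("robust interval requested but robust_vcov not computed")
    half = _tcrit(fit.df, alpha) * math.sqrt(float(vcov[1, 1]))
    return IntervalResult(
        lower=fit.beta_star - half,
        upper=fit.beta_star + half,
        defined=True,
        method="naive",
        alpha_level=alpha,
    )


Calibs = Union[CalibrationFit, Tuple[CalibrationFit, CalibrationFit]]


def _differential_trial_vcov(fit: NaiveFit) -> np.ndarray:
    if fit.robust_vcov is None:
        raise DataValidationError(
            "differential intervals require the HC3 vcov; call hc3_vcov first"
        )
    return fit.robust_vcov


def _interval_around(beta: float, var: float, df: int, alpha: float, method: str) -> IntervalResult:
    half = _tcrit(df, alpha) * math.sqrt(var)
    return IntervalResult(
        lower=beta - half,
        upper=beta + half,
        defined=True,
        method=method,
        alpha_level=alpha,
    )


def ci_zero_variance(
    est: CorrectedEstimate, fit: NaiveFit, calibs: Calibs, alpha: float = 0.05
) -> IntervalResult:
    """Interval treating all estimated calibration parameters as constants."""
    if est.method == "systematic_corrected":
        calib = calibs if isinstance(calibs, CalibrationFit) else calibs[0]
        var = float(fit.vcov[1, 1]) / calib.theta1_hat**2
    elif est.method == "differential_corrected":
        calib0, calib1 = calibs
        a = 1.0 / calib1.theta1_hat - 1.0 / calib0.theta1_hat
        b = 1.0 / calib1.theta1_hat
        v = _differential_trial_vcov(fit)
        var = a**2 * float(v[0, 0]) + b**2 * float(v[1, 1]) + 2.0 * a * b * float(v[0, 1])
    else:
        raise DataValidationError(f"no zero-variance interval for method {est.method!r}")
    return _interval_around(est.beta_hat, var, fit.df, alpha, "zero_variance")


def ci_delta(
    est: CorrectedEstimate, fit: NaiveFit, calibs: Calibs, alpha: float = 0.05
) -> IntervalResult:
    """First-order Taylor (delta-method) interval for the corrected effect.

    The trial fit and each calibration-arm fit come from independent samples,
    so the joint vcov is block-diagonal: the trial block (model-based for
    systematic error, HC3 for differential) and the per-arm calibration OLS
    blocks including the intercept-slope covariance.
    """
    if est.method == "systematic_corrected":
        calib = calibs if isinstance(calibs, CalibrationFit) else calibs[0]
        t1 = calib.theta1_hat
        var = (
            float(fit.vcov[1, 1]) / t1**2
            + fit.beta_star**2 * float(calib.vcov[1, 1]) / t1**4
        )
    elif est.method == "differential_corrected":
        calib0, calib1 = calibs
        t10, t11 = calib0.theta1_hat, calib1.theta1_hat
        # gradient of beta_hat in (alpha*, beta*, theta00, theta10, theta01, theta11)
        g_trial = np.array([1.0 / t11 - 1.0 / t10, 1.0 / t11])
        g_c0 = np.array(
            [1.0 / t10, (fit.alpha_star - calib0.theta0_hat) / t10**2]
        )
        g_c1 = np.array(
            [
                -1.0 / t11,
                -(fit.beta_star + fit.alpha_star - calib1.theta0_hat) / t11**2,
            ]
        )
        v_trial = _differential_trial_vcov(fit)
        var = float(
            g_trial @ v_trial @ g_trial
            + g_c0 @ calib0.vcov @ g_c0
            + g_c1 @ calib1.vcov @ g_c1
        )
    else:
        raise DataValidationError(f"no delta interval for method {est.method!r}")
    return _interval_around(est.beta_hat, var, fit.df, alpha, "delta")


def ci_fieller(fit: NaiveFit, calib: CalibrationFit, alpha: float = 0.05) -> IntervalResult:
    """Fieller interval for beta_Y*/theta1 (systematic structure only).

    Bounds are the roots in rho of

        (beta_Y* - rho * theta1_hat)^2 = t^2 (Var(beta_Y*) + rho^2 Var(theta1_hat)),

    with zero covariance between numerator and denominator (independent
    samples).  The interval is a bounded set iff theta1_hat^2 >
    t^2 Var(theta1_hat), i.e. |theta1_hat|/SE > t; otherwise the confidence
    set is unbounded and ``defined=False`` is returned with NaN bounds.
    """
    t = _tcrit(fit.df, alpha)
    vb = float(fit.vcov[1, 1])
    vt = float(calib.vcov[1, 1])
    t1 = calib.theta1_hat
    b = fit.beta_star
    lead = t1**2 - t**2 * vt
    if lead <= 0.0:
        return IntervalResult(
            lower=math.nan,
            upper=math.nan,
            defined=False,
            method="fieller",
            alpha_level=alpha,
        )
    disc = t**2 * (vb * lead + vt * b**2)
    root = math.sqrt(disc)
    lower = (b * t1 - root) / lead
    upper = (b * t1 + root) / lead
    return IntervalResult(
        lower=lower, upper=upper, defined=True, method="fieller", alpha_level=alpha
    )


# ---------------------------------------------------------------------------
# bootstrap


def _bootstrap_calibration_fits(
    y_true: np.ndarray, y_star: np.ndarray, b: int, rng: np.random.Generator
):
    """Vectorised OLS of y_star on y_true over b with-replacement resamples.

    Returns (intercepts, slopes, valid) where ``valid`` flags resamples with
    a non-constant y_true draw.
    """
    k = y_true.shape[0]
    idx = rng.integers(0, k, size=(b, k))
    t = y_true[idx]
    s = y_star[idx]
    mt = t.mean(axis=1)
    ms = s.mean(axis=1)
    dt = t - mt[:, None]
    syy = (dt**2).sum(axis=1)
    valid = syy > 0.0
    sxy = (dt * (s - ms[:, None])).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = np.where(valid, sxy / np.where(valid, syy, 1.0), np.nan)
    intercept = ms - slope * mt
    return intercept, slope, valid


def ci_bootstrap(
    trial: TrialDataset,
    calib: CalibrationDataset,
    structure: str,
    b: int,
    alpha: float,
    rng: np.random.Generator,
) -> IntervalResult:
    """Percentile bootstrap interval for the corrected treatment effect.

    Trial rows are resampled with replacement *within each arm* (allocation
    is fixed by design); calibration rows are resampled independently (within
    each arm for the differential structure).  Resamples whose calibration
    regression is degenerate are dropped; the interval is formed from the
    (alpha/2, 1 - alpha/2) percentiles of the retained corrected estimates.
    Negative resampled slopes are retained (sign flips propagate).
    """
    if trial.y_star is None:
        raise DataValidationError("trial has no observed endpoint y_star")
    y = trial.y_star
    x = trial.x
    y0 = y[x == 0]
    y1 = y[x == 1]
    n0, n1 = y0.shape[0], y1.shape[0]
    idx0 = rng.integers(0, n0, size=(b, n0))
    idx1 = rng.integers(0, n1, size=(b, n1))
    alpha_star = y0[idx0].mean(axis=1)
    beta_star = y1[idx1].mean(axis=1) - alpha_star

    if structure == "systematic":
        icept, slope, valid = _bootstrap_calibration_fits(calib.y_true, calib.y_star, b, rng)
        valid &= slope != 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            betas = beta_star / slope
    elif structure == "differential":
        if calib.x is None:
            raise DataValidationError("differential bootstrap requires a two-arm calibration set")
        m0 = calib.x == 0
        i0, s0, v0 = _bootstrap_calibration_fits(calib.y_true[m0], calib.y_star[m0], b, rng)
        i1, s1, v1 = _bootstrap_calibration_fits(calib.y_true[~m0], calib.y_star[~m0], b, rng)
        valid = v0 & v1 & (s0 != 0.0) & (s1 != 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_hat = (alpha_star - i0) / s0
            betas = (beta_star + alpha_star - i1) / s1 - alpha_hat
    else:
        raise DataValidationError(f"unknown correction structure {structure!r}")

    kept = betas[valid]
    effective_b = int(kept.shape[0])
    if effective_b == 0:
        raise BootstrapFailureError("all bootstrap resamples were degenerate")
    lower, upper = np.quantile(kept, [alpha / 2.0, 1.0 - alpha / 2.0])
    return IntervalResult(
        lower=float(lower),
        upper=float(upper),
        defined=True,
        method="bootstrap",
        alpha_level=alpha,
        effective_b=effective_b,
    )
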