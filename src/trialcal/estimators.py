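"""Naive and measurement-error-corrected treatment-effect estimators.

The naive analysis regresses the error-prone endpoint Y* on treatment X,

    Y* = alpha_Y* + beta_Y* X + delta,

estimated by OLS.  For a two-group design the OLS solution is the closed
form beta_Y* = mean(Y*|X=1) - mean(Y*|X=0), which this module uses directly
(exact and fast inside the Monte-Carlo engine); a generic-design path exists
for the covariate-adjusted analysis.

The corrected estimators divide out the error-model parameters estimated by
OLS on an external calibration sample (regression of Y* on Y):

* systematic error (one calibration fit, theta0/theta1):
      alpha_Y = (alpha_Y* - theta0_hat) / theta1_hat
      beta_Y  = beta_Y* / theta1_hat
* differential error (per-arm calibration fits):
      alpha_Y = (alpha_Y* - theta00_hat) / theta10_hat
      beta_Y  = (beta_Y* + alpha_Y* - theta01_hat) / theta11_hat - alpha_Y

Estimated calibration slopes are propagated as-is, however small: the heavy
tails of the corrected estimator at small calibration sizes are a genuine
property of the ratio, not an artefact to be truncated.  Only an exactly
zero slope raises :class:`~trialcal.errors.UndefinedCorrectionError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np

from .datagen import CalibrationDataset
from .errors import (
    DataValidationError,
    DegenerateDesignError,
    SingularCalibrationError,
    SingularDesignError,
    UndefinedCorrectionError,
)

__all__ = [
    "NaiveFit",
    "CalibrationFit",
    "CorrectedEstimate",
    "AdjustedFit",
    "fit_ols",
    "fit_ols_adjusted",
    "hc3_vcov",
    "fit_calibration",
    "fit_calibration_by_arm",
    "correct_systematic",
    "correct_differential",
    "reliability_sample_size",
]


@dataclass
class NaiveFit:
    """Two-group OLS fit of the observed endpoint on treatment."""

    alpha_star: float
    beta_star: float
    vcov: np.ndarray  # model-based OLS vcov of (alpha_star, beta_star)
    n: int
    df: int
    residual_sd: float
    n0: int
    n1: int
    robust_vcov: Optional[np.ndarray] = None  # HC3, filled by hc3_vcov


@dataclass
class CalibrationFit:
    """OLS fit of the error-prone endpoint on the error-free endpoint."""

    theta0_hat: float
    theta1_hat: float
    vcov: np.ndarray  # OLS vcov of (theta0_hat, theta1_hat)
    k: int
    df: int
    syy: float  # sum of squared deviations of y_true
    residual_sd: float


@dataclass
class CorrectedEstimate:
    """Corrected (or naive) point estimates with per-method intervals."""

    alpha_hat: float
    beta_hat: float
    method: str  # naive | systematic_corrected | differential_corrected
    intervals: Dict[str, "IntervalLike"] = field(default_factory=dict)
    alpha_level: float = 0.05


# typing-only protocol; the concrete class lives in ci_methods
IntervalLike = object


def _arm_split(y: np.ndarray, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    mask = x == 1
    return y[~mask], y[mask]


def fit_ols(y, x) -> NaiveFit:
    """OLS of y on a binary treatment indicator, via the two-group closed form.

    The slope equals the difference in arm means; the model-based vcov uses
    the pooled residual variance with n - 2 degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x)
    if y.shape != x.shape or y.ndim != 1:
        raise DataValidationError("y and x must be equal-length vectors")
    n = y.shape[0]
    if n < 4:
        raise DataValidationError("need at least 4 observations")
    y0, y1 = _arm_split(y, x)
    n0, n1 = y0.shape[0], y1.shape[0]
    if n0 == 0 or n1 == 0:
        raise SingularDesignError("treatment indicator is constant")
    m0 = float(y0.mean())
    m1 = float(y1.mean())
    rss = float(((y0 - m0) ** 2).sum() + ((y1 - m1) ** 2).sum())
    df = n - 2
    s2 = rss / df
    vcov = s2 * np.array([[1.0 / n0, -1.0 / n0], [-1.0 / n0, 1.0 / n0 + 1.0 / n1]])
    return NaiveFit(
        alpha_star=m0,
        beta_star=m1 - m0,
        vcov=vcov,
        n=n,
        df=df,
        residual_sd=math.sqrt(s2),
        n0=n0,
        n1=n1,
    )


def hc3_vcov(fit: NaiveFit, y, x) -> np.ndarray:
    """HC3 sandwich vcov of (alpha_star, beta_star); stored on ``fit``.

    For the two-group design the leverage of every observation in arm g is
    1/n_g, so the HC3 variance of an arm mean is sum(e_i^2 / (1 - 1/n_g)^2)
    / n_g^2; alpha_star is the arm-0 mean and beta_star the difference of
    the two independent arm means.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x)
    y0, y1 = _arm_split(y, x)
    if y0.shape[0] < 2 or y1.shape[0] < 2:
        raise DegenerateDesignError("HC3 undefined with an arm of size 1 (leverage = 1)")
    parts = []
    for yg in (y0, y1):
        ng = yg.shape[0]
        e = yg - yg.mean()
        h = 1.0 / ng
        parts.append(float((e**2 / (1.0 - h) ** 2).sum()) / ng**2)
    v0, v1 = parts
    robust = np.array([[v0, -v0], [-v0, v0 + v1]])
    fit.robust_vcov = robust
    return robust


@dataclass
class AdjustedFit:
    """Generic OLS fit of y on (1, x, extra columns); used for the
    covariate-conditional analysis."""

    coef: np.ndarray
    vcov: np.ndarray
    n: int
    df: int
    residual_sd: float

    @property
    def beta_x(self) -> float:
        """Treatment coefficient (x is always the second column)."""
        return float(self.coef[1])

    @property
    def var_beta_x(self) -> float:
        return float(self.vcov[1, 1])


def fit_ols_adjusted(y, x, s=None) -> AdjustedFit:
    """OLS of y on treatment and an optional extra binary covariate.

    A constant covariate column (e.g. the prognostic factor is absent from
    the sample) is dropped, so the fit degrades gracefully to the unadjusted
    regression.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    cols = [np.ones_like(y), x]
    if s is not None:
        s = np.asarray(s, dtype=float)
        if s.min() != s.max():  # drop constant column
            cols.append(s)
    design = np.column_stack(cols)
    n, p = design.shape
    if n <= p:
        raise DataValidationError("too few observations for the adjusted fit")
    xtx = design.T @ design
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError("singular design matrix") from exc
    coef = xtx_inv @ (design.T @ y)
    resid = y - design @ coef
    df = n - p
    s2 = float(resid @ resid) / df
    return AdjustedFit(coef=coef, vcov=s2 * xtx_inv, n=n, df=df, residual_sd=math.sqrt(s2))


def fit_calibration(calib: CalibrationDataset) -> CalibrationFit:
    """OLS regression of the error-prone on the error-free endpoint."""
    return _fit_calibration_arrays(calib.y_true, calib.y_star)


def _fit_calibration_arrays(y_true: np.ndarray, y_star: np.ndarray) -> CalibrationFit:
    k = y_true.shape[0]
    if k < 3:
        raise DataValidationError("calibration requires at least 3 subjects")
    mt = float(y_true.mean())
    ms = float(y_star.mean())
    dt = y_true - mt
    syy = float((dt**2).sum())
    if syy == 0.0:
        raise SingularCalibrationError("y_true is constant; calibration slope undefined")
    slope = float((dt * (y_star - ms)).sum()) / syy
    intercept = ms - slope * mt
    resid = y_star - intercept - slope * y_true
    df = k - 2
    s2 = float(resid @ resid) / df
    vcov = s2 * np.array(
        [[1.0 / k + mt**2 / syy, -mt / syy], [-mt / syy, 1.0 / syy]]
    )
    return CalibrationFit(
        theta0_hat=intercept,
        theta1_hat=slope,
        vcov=vcov,
        k=k,
        df=df,
        syy=syy,
        residual_sd=math.sqrt(s2),
    )


def fit_calibration_by_arm(
    calib: CalibrationDataset,
) -> Tuple[CalibrationFit, CalibrationFit]:
    """Independent per-arm calibration fits (differential correction).

    Arm 0 estimates (theta00, theta10); arm 1 estimates (theta01, theta11).
    Singularities are reported per arm.
    """
    if calib.x is None:
        raise DataValidationError("two-arm calibration requires the arm label x")
    fits = []
    for arm in (0, 1):
        mask = calib.x == arm
        try:
            fits.append(_fit_calibration_arrays(calib.y_true[mask], calib.y_star[mask]))
        except SingularCalibrationError as exc:
            raise SingularCalibrationError(f"arm {arm}: {exc}") from exc
    return fits[0], fits[1]


def correct_systematic(fit: NaiveFit, calib: CalibrationFit) -> CorrectedEstimate:
    """Corrected point estimates under systematic error.

    alpha = (alpha_Y* - theta0_hat)/theta1_hat, beta = beta_Y*/theta1_hat.
    A negative estimated slope flips the sign of the corrected effect; this
    is propagated, not suppressed.
    """
    t1 = calib.theta1_hat
    if t1 == 0.0:
        raise UndefinedCorrectionError("estimated calibration slope is exactly zero")
    return CorrectedEstimate(
        alpha_hat=(fit.alpha_star - calib.theta0_hat) / t1,
        beta_hat=fit.beta_star / t1,
        method="systematic_corrected",
    )


def correct_differential(
    fit: NaiveFit, calib0: CalibrationFit, calib1: CalibrationFit
) -> CorrectedEstimate:
    """Corrected point estimates under differential error (per-arm fits)."""
    t10 = calib0.theta1_hat
    t11 = calib1.theta1_hat
    if t10 == 0.0 or t11 == 0.0:
        raise UndefinedCorrectionError("an estimated calibration slope is exactly zero")
    alpha_hat = (fit.alpha_star - calib0.theta0_hat) / t10
    beta_hat = (fit.beta_star + fit.alpha_star - calib1.theta0_hat) / t11 - alpha_hat
    return CorrectedEstimate(
        alpha_hat=alpha_hat, beta_hat=beta_hat, method="differential_corrected"
    )


def reliability_sample_size(n: int, r: float) -> int:
    """Inflated sample size N/R compensating classical error of reliability r.

    r is the reliability coefficient: the share of observed-endpoint variance
    attributable to the true endpoint.  Rounded up to a whole participant.
    """
    if not 0.0 < r <= 1.0:
        raise ValueError(f"reliability must be in (0, 1], got {r}")
    if n <= 0:
        raise ValueError("n must be positive")
    return math.ceil(n / r)
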