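"""Synthetic two-arm trial endpoints under explicit measurement-error models.

The true continuous endpoint of participant *i* in a two-arm randomised trial
follows the linear model

    Y = alpha_Y + beta_Y * X + gamma * S + eps,    eps ~ N(0, sigma^2) iid,

with X in {0, 1} the treatment indicator, and S an optional binary prognostic
factor (gamma = 0 by default).  What is recorded is an error-prone surrogate
Y* whose relation to Y is one of five structures:

==================  =====================================================
classical           Y* = Y + e,                     e ~ N(0, tau^2)
heteroscedastic     Y* = Y + e,                     SD tau0 / tau1 by arm
systematic          Y* = theta0 + theta1*Y + e,     e ~ N(0, tau^2)
differential        Y* = theta0X + theta1X*Y + eX,  all parameters by arm
covariate_additive  Y* = Y + shift*S + e,           e ~ N(0, tau^2)
==================  =====================================================

Besides the simulators this module carries the small analytic results that
parameterise and verify simulations: the probability limit of the naive OLS
slope of Y* on X, the residual SD of that naive regression, and the error SD
``tau`` that yields a prescribed squared correlation (R^2) between Y* and Y
within a treatment arm.

The R^2 convention is *conditional on treatment*: R^2 = theta1^2 sigma^2 /
(theta1^2 sigma^2 + tau^2), i.e. the coefficient of determination of the
calibration regression of Y* on Y at fixed X, not the marginal one (which
would mix in the treatment-effect variance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ConfigError, DataValidationError, InvalidModelError

__all__ = [
    "OutcomeModel",
    "ErrorModel",
    "TrialDataset",
    "CalibrationDataset",
    "generate_trial",
    "apply_error",
    "generate_calibration",
    "tau_for_r2",
    "expected_naive_slope",
    "expected_residual_sd",
]

ERROR_KINDS = (
    "classical",
    "heteroscedastic",
    "systematic",
    "differential",
    "covariate_additive",
)


@dataclass(frozen=True)
class OutcomeModel:
    """True-endpoint generating model.

    Parameters
    ----------
    alpha_y : float
        Intercept: mean endpoint in the control arm (endpoint units; g/L in
        the haemoglobin running example).
    beta_y : float
        True treatment effect (difference in arm means).
    sigma : float
        Residual SD of the endpoint, > 0.
    covariate_effect : float, default 0
        Coefficient of the binary prognostic factor S.
    covariate_prevalence : float, default 0
        P(S = 1), identical in both arms by randomisation.
    """

    alpha_y: float
    beta_y: float
    sigma: float
    covariate_effect: float = 0.0
    covariate_prevalence: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise InvalidModelError(f"sigma must be > 0, got {self.sigma}")
        if not 0.0 <= self.covariate_prevalence <= 1.0:
            raise InvalidModelError(
                f"covariate_prevalence must be in [0, 1], got {self.covariate_prevalence}"
            )


@dataclass(frozen=True)
class ErrorModel:
    """Mapping from the true endpoint Y to the observed surrogate Y*.

    Only the fields relevant to ``kind`` are read; the constructors
    :meth:`classical`, :meth:`heteroscedastic`, :meth:`systematic`,
    :meth:`differential` and :meth:`covariate_additive` set exactly those.
    """

    kind: str
    theta0: float = 0.0
    theta1: float = 1.0
    tau: Optional[float] = None
    theta00: float = 0.0
    theta01: float = 0.0
    theta10: float = 1.0
    theta11: float = 1.0
    tau0: Optional[float] = None
    tau1: Optional[float] = None
    covariate_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ERROR_KINDS:
            raise InvalidModelError(f"unknown error kind {self.kind!r}")
        if self.kind in ("classical", "systematic", "covariate_additive"):
            if self.tau is None or not self.tau > 0:
                raise InvalidModelError(f"{self.kind} error requires tau > 0")
        if self.kind in ("heteroscedastic", "differential"):
            if self.tau0 is None or self.tau1 is None or not (self.tau0 > 0 and self.tau1 > 0):
                raise InvalidModelError(f"{self.kind} error requires tau0 > 0 and tau1 > 0")
        if self.kind == "systematic" and self.theta1 == 0:
            raise InvalidModelError("systematic error requires theta1 != 0")
        if self.kind == "differential" and (self.theta10 == 0 or self.theta11 == 0):
            raise InvalidModelError("differential error requires theta10 != 0 and theta11 != 0")

    @classmethod
    def classical(cls, tau: float) -> "ErrorModel":
        return cls(kind="classical", tau=tau)

    @classmethod
    def heteroscedastic(cls, tau0: float, tau1: float) -> "ErrorModel":
        return cls(kind="heteroscedastic", tau0=tau0, tau1=tau1)

    @classmethod
    def systematic(cls, theta0: float, theta1: float, tau: float) -> "ErrorModel":
        return cls(kind="systematic", theta0=theta0, theta1=theta1, tau=tau)

    @classmethod
    def differential(
        cls,
        theta00: float,
        theta01: float,
        theta10: float,
        theta11: float,
        tau0: float,
        tau1: float,
    ) -> "ErrorModel":
        return cls(
            kind="differential",
            theta00=theta00,
            theta01=theta01,
            theta10=theta10,
            theta11=theta11,
            tau0=tau0,
            tau1=tau1,
        )

    @classmethod
    def covariate_additive(cls, covariate_shift: float, tau: float) -> "ErrorModel":
        return cls(kind="covariate_additive", covariate_shift=covariate_shift, tau=tau)


def _as_float_vector(name: str, values, errors: list) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        errors.append(f"{name} must be one-dimensional")
    if np.any(~np.isfinite(arr)):
        errors.append(f"{name} contains non-finite values")
    return arr


@dataclass
class TrialDataset:
    """Participant-level trial data: treatment x, observed y_star, and (in
    simulations only) the latent y_true and optional prognostic factor s."""

    x: np.ndarray
    y_star: Optional[np.ndarray] = None
    y_true: Optional[np.ndarray] = None
    s: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        errors: list = []
        self.x = np.asarray(self.x, dtype=int)
        if self.x.ndim != 1:
            errors.append("x must be one-dimensional")
        if not np.isin(self.x, (0, 1)).all():
            errors.append("x must contain only 0/1")
        n = self.x.shape[0]
        if n < 4:
            errors.append(f"need at least 4 participants, got {n}")
        elif self.x.sum() == 0 or self.x.sum() == n:
            errors.append("both arms must be non-empty")
        for name in ("y_star", "y_true"):
            vec = getattr(self, name)
            if vec is not None:
                vec = _as_float_vector(name, vec, errors)
                if vec.shape[0] != n:
                    errors.append(f"{name} length {vec.shape[0]} != x length {n}")
                setattr(self, name, vec)
        if self.s is not None:
            self.s = np.asarray(self.s, dtype=int)
            if self.s.shape != self.x.shape:
                errors.append("s must match x in length")
            elif not np.isin(self.s, (0, 1)).all():
                errors.append("s must contain only 0/1")
        if errors:
            raise DataValidationError(errors)

    @property
    def n(self) -> int:
        return int(self.x.shape[0])


@dataclass
class CalibrationDataset:
    """External calibration sample: the error-free endpoint y_true and the
    error-prone surrogate y_star on the same subjects; the arm label x is
    present only for the two-arm ("small pilot study") design needed by the
    differential correction."""

    y_true: np.ndarray
    y_star: np.ndarray
    x: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        errors: list = []
        self.y_true = _as_float_vector("y_true", self.y_true, errors)
        self.y_star = _as_float_vector("y_star", self.y_star, errors)
        k = self.y_true.shape[0]
        if self.y_star.shape[0] != k:
            errors.append("y_true and y_star must have equal length")
        if k < 3:
            errors.append(f"need at least 3 calibration subjects, got {k}")
        if self.x is not None:
            self.x = np.asarray(self.x, dtype=int)
            if self.x.shape[0] != k:
                errors.append("x must match y_true in length")
            elif not np.isin(self.x, (0, 1)).all():
                errors.append("x must contain only 0/1")
            else:
                for arm in (0, 1):
                    if int((self.x == arm).sum()) < 3:
                        errors.append(f"need at least 3 calibration subjects in arm {arm}")
        if errors:
            raise DataValidationError(errors)

    @property
    def k(self) -> int:
        return int(self.y_true.shape[0])


# ---------------------------------------------------------------------------
# simulators


def generate_trial(
    model: OutcomeModel, n_per_arm: int, rng: np.random.Generator
) -> TrialDataset:
    """Simulate the true endpoint for a balanced two-arm trial.

    Allocation is a deterministic equal split (n_per_arm per arm), matching a
    trial whose participants are equally divided over the arms; S, when
    present, is drawn iid Bernoulli independently of treatment.  ``y_star``
    is left unset — apply an error model to observe the surrogate.
    """
    if n_per_arm < 2:
        raise DataValidationError("n_per_arm must be >= 2")
    n = 2 * n_per_arm
    x = np.repeat([0, 1], n_per_arm)
    s = None
    y = model.alpha_y + model.beta_y * x.astype(float)
    if model.covariate_prevalence > 0 or model.covariate_effect != 0:
        s = rng.binomial(1, model.covariate_prevalence, size=n)
        y = y + model.covariate_effect * s
    y = y + rng.normal(0.0, model.sigma, size=n)
    return TrialDataset(x=x, y_true=y, s=s)


def _observe(
    y_true: np.ndarray,
    x: np.ndarray,
    s: Optional[np.ndarray],
    error: ErrorModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Map true endpoints to observed surrogates under ``error`` (vectorised)."""
    n = y_true.shape[0]
    kind = error.kind
    if kind == "classical":
        return y_true + rng.normal(0.0, error.tau, size=n)
    if kind == "heteroscedastic":
        sd = np.where(x == 1, error.tau1, error.tau0)
        return y_true + rng.standard_normal(n) * sd
    if kind == "systematic":
        return error.theta0 + error.theta1 * y_true + rng.normal(0.0, error.tau, size=n)
    if kind == "differential":
        intercept = np.where(x == 1, error.theta01, error.theta00)
        slope = np.where(x == 1, error.theta11, error.theta10)
        sd = np.where(x == 1, error.tau1, error.tau0)
        return intercept + slope * y_true + rng.standard_normal(n) * sd
    if kind == "covariate_additive":
        if s is None:
            raise DataValidationError("covariate_additive error requires the prognostic factor s")
        return (
            y_true
            + error.covariate_shift * s.astype(float)
            + rng.normal(0.0, error.tau, size=n)
        )
    raise InvalidModelError(f"unknown error kind {kind!r}")  # pragma: no cover


def apply_error(
    trial: TrialDataset, error: ErrorModel, rng: np.random.Generator
) -> TrialDataset:
    """Return a copy of ``trial`` with ``y_star`` drawn from the error model.

    ``y_true`` is preserved unchanged; estimators never read it.
    """
    if trial.y_true is None:
        raise DataValidationError("trial has no y_true; generate it before applying error")
    y_star = _observe(trial.y_true, trial.x, trial.s, error, rng)
    return replace(trial, y_star=y_star)


def generate_calibration(
    model: OutcomeModel,
    error: ErrorModel,
    k: int,
    design: str,
    rng: np.random.Generator,
) -> CalibrationDataset:
    """Simulate an external calibration sample of size ``k``.

    ``design="placebo_only"`` draws all subjects with the characteristics of
    the control arm (no treatment term; the arm-0 error mapping applies);
    ``design="two_arm"`` emulates a small pilot study with k/2 subjects per
    arm and records the arm label, as required by the differential correction.
    """
    if design == "placebo_only":
        if k < 3:
            raise ConfigError("placebo_only calibration requires k >= 3")
        x = np.zeros(k, dtype=int)
        record_x = None
    elif design == "two_arm":
        if k < 6 or k % 2 != 0:
            raise ConfigError("two_arm calibration requires even k >= 6")
        x = np.repeat([0, 1], k // 2)
        record_x = x
    else:
        raise ConfigError(f"unknown calibration design {design!r}")

    s = None
    y = model.alpha_y + model.beta_y * x.astype(float)
    if model.covariate_prevalence > 0 or model.covariate_effect != 0:
        s = rng.binomial(1, model.covariate_prevalence, size=k)
        y = y + model.covariate_effect * s
    y = y + rng.normal(0.0, model.sigma, size=k)
    y_star = _observe(y, x, s, error, rng)
    return CalibrationDataset(y_true=y, y_star=y_star, x=record_x)


# ---------------------------------------------------------------------------
# analytic mappings


def tau_for_r2(theta1: float, sigma: float, r2: float) -> float:
    """Error SD tau giving squared correlation ``r2`` between Y* and Y within
    a treatment arm, for surrogate slope ``theta1`` and endpoint SD ``sigma``.

    Inverts R^2 = theta1^2 sigma^2 / (theta1^2 sigma^2 + tau^2), i.e.
    tau = |theta1| * sigma * sqrt((1 - R^2) / R^2).
    """
    if not 0.0 < r2 < 1.0:
        raise ValueError(f"r2 must be in (0, 1), got {r2}")
    if theta1 == 0:
        raise ValueError("theta1 must be non-zero")
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    return abs(theta1) * sigma * math.sqrt((1.0 - r2) / r2)


def expected_naive_slope(model: OutcomeModel, error: ErrorModel) -> float:
    """Probability limit of the naive OLS slope of Y* on X.

    classical / heteroscedastic / covariate_additive (equal prevalence in
    both arms): beta_Y; systematic: theta1 * beta_Y; differential:
    theta01 - theta00 + (theta11 - theta10) * m0 + theta11 * beta_Y with m0
    the control-arm mean of Y.
    """
    if error.kind in ("classical", "heteroscedastic", "covariate_additive"):
        return model.beta_y
    if error.kind == "systematic":
        return error.theta1 * model.beta_y
    if error.kind == "differential":
        m0 = model.alpha_y + model.covariate_effect * model.covariate_prevalence
        return (
            error.theta01
            - error.theta00
            + (error.theta11 - error.theta10) * m0
            + error.theta11 * model.beta_y
        )
    raise InvalidModelError(f"unknown error kind {error.kind!r}")  # pragma: no cover


def expected_residual_sd(model: OutcomeModel, error: ErrorModel, arm: int) -> float:
    """SD of the residual of the naive regression of Y* on X in one arm.

    classical: sqrt(sigma^2 + tau^2); systematic: sqrt(theta1^2 sigma^2 +
    tau^2); differential: sqrt(theta1X^2 sigma^2 + tauX^2); the prognostic
    factor, when present, contributes its own Bernoulli variance to the
    residual of the unadjusted regression.
    """
    if arm not in (0, 1):
        raise ValueError("arm must be 0 or 1")
    p = model.covariate_prevalence
    cov_var = p * (1.0 - p)
    kind = error.kind
    if kind == "classical":
        slope, tau = 1.0, error.tau
        gamma = model.covariate_effect
    elif kind == "heteroscedastic":
        slope, tau = 1.0, (error.tau1 if arm == 1 else error.tau0)
        gamma = model.covariate_effect
    elif kind == "systematic":
        slope, tau = error.theta1, error.tau
        gamma = error.theta1 * model.covariate_effect
    elif kind == "differential":
        slope = error.theta11 if arm == 1 else error.theta10
        tau = error.tau1 if arm == 1 else error.tau0
        gamma = slope * model.covariate_effect
    elif kind == "covariate_additive":
        slope, tau = 1.0, error.tau
        gamma = model.covariate_effect + error.covariate_shift
    else:  # pragma: no cover
        raise InvalidModelError(f"unknown error kind {kind!r}")
    return math.sqrt(slope**2 * model.sigma**2 + gamma**2 * cov_var + tau**2)
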