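"""Monte-Carlo scenario engine and performance metrics.

A scenario fixes a true-endpoint model, an error structure, a trial size, a
calibration-sample size and design, and a set of interval methods.  Each
replication generates a trial, observes the error-prone endpoint, generates
a fresh external calibration sample, computes the naive and corrected
analyses with all requested intervals, and the engine aggregates

* percentage bias 100 (mean estimate - estimand)/estimand,
* empirical SE (sample SD over replications),
* root mean squared error,
* per-method coverage of the estimand and average interval width,
* Type-II error (interval contains the null) or Type-I error (interval
  excludes the null when the estimand equals it),

each with its Monte-Carlo standard error (standard simulation-study
conventions).  Fieller intervals may be undefined in some replications; the
undefined share is reported, coverage and width are computed over defined
intervals only, and both are suppressed (NaN) when more than 5% of
replications fail — comparisons against always-defined methods would
otherwise be unfair.

Reproducibility: replication r of a scenario with seed s draws from the
dedicated substream ``SeedSequence(s, spawn_key=(r,))``, so results are
independent of execution order and any single replication can be replayed
in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .ci_methods import (
    IntervalResult,
    ci_bootstrap,
    ci_delta,
    ci_fieller,
    ci_zero_variance,
    naive_wald_interval,
)
from .datagen import (
    CalibrationDataset,
    ErrorModel,
    OutcomeModel,
    TrialDataset,
    apply_error,
    generate_calibration,
    generate_trial,
    tau_for_r2,
)
from .errors import (
    BootstrapFailureError,
    ConfigError,
    SingularCalibrationError,
    UndefinedCorrectionError,
)
from .estimators import (
    correct_differential,
    correct_systematic,
    fit_calibration,
    fit_calibration_by_arm,
    fit_ols,
    fit_ols_adjusted,
    hc3_vcov,
)

__all__ = [
    "ScenarioConfig",
    "PerformanceSummary",
    "ScenarioResult",
    "PrognosticResult",
    "correct_trial",
    "run_scenario",
    "compute_metrics",
    "preset_scenarios",
    "run_prognostic_experiment",
    "FIELLER_SUPPRESSION_THRESHOLD",
]

CI_METHOD_NAMES = ("zero_variance", "delta", "fieller", "bootstrap")

#: Fieller coverage/width are suppressed above this undefined-rate (%).
FIELLER_SUPPRESSION_THRESHOLD = 5.0


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one Monte-Carlo scenario.

    ``k_calibration = 0`` requests a naive-only scenario (no calibration
    sample is generated and no corrected analysis is run).
    """

    outcome_model: OutcomeModel
    error_model: ErrorModel
    n_per_arm: int
    k_calibration: int
    calibration_design: str = "placebo_only"
    n_reps: int = 10_000
    ci_methods: Tuple[str, ...] = ()
    alpha: float = 0.05
    bootstrap_b: int = 999
    seed: int = 0

    def __post_init__(self) -> None:
        problems: List[str] = []
        if self.n_per_arm < 2:
            problems.append("n_per_arm must be >= 2")
        if self.k_calibration < 0:
            problems.append("k_calibration must be >= 0")
        if self.calibration_design not in ("placebo_only", "two_arm"):
            problems.append(f"unknown calibration_design {self.calibration_design!r}")
        if self.error_model.kind == "differential" and self.k_calibration > 0:
            if self.calibration_design != "two_arm":
                problems.append(
                    "differential error requires the two_arm calibration design "
                    "(a small pilot study with both treatments allocated)"
                )
        if self.calibration_design == "two_arm" and self.k_calibration % 2 != 0:
            problems.append("k_calibration must be even for the two_arm design")
        unknown = set(self.ci_methods) - set(CI_METHOD_NAMES)
        if unknown:
            problems.append(f"unknown ci methods: {sorted(unknown)}")
        if "fieller" in self.ci_methods and self.error_model.kind == "differential":
            problems.append("the Fieller interval applies to the systematic structure only")
        if not 0.0 < self.alpha < 1.0:
            problems.append("alpha must be in (0, 1)")
        if self.bootstrap_b < 1:
            problems.append("bootstrap_b must be positive")
        if self.n_reps < 1:
            problems.append("n_reps must be positive")
        if problems:
            raise ConfigError(problems)


@dataclass
class PerformanceSummary:
    """Per-scenario Monte-Carlo metrics for one estimator."""

    percentage_bias: float
    emp_se: float
    sqrt_mse: float
    coverage: Dict[str, float]
    avg_ci_width: Dict[str, float]
    type2_error: Dict[str, float]
    type1_error: Optional[Dict[str, float]]
    fieller_failure_rate: float
    bootstrap_degeneracy_rate: float
    mcse_bias: float
    mcse_emp_se: float
    mcse_mse: float
    mcse_coverage: Dict[str, float]
    n_reps: int
    estimand: float
    mean_estimate: float


@dataclass
class ScenarioResult:
    """Naive and (when a calibration set is used) corrected summaries."""

    naive: PerformanceSummary
    corrected: Optional[PerformanceSummary]
    n_failed_corrections: int = 0


def compute_metrics(
    estimates: Sequence[float],
    intervals: Mapping[str, Sequence[IntervalResult]],
    estimand: float,
    null_value: float = 0.0,
    bootstrap_b: Optional[int] = None,
) -> PerformanceSummary:
    """Aggregate replication-level estimates and intervals into a summary."""
    est = np.asarray(estimates, dtype=float)
    n = est.shape[0]
    if n < 2:
        raise ConfigError("need at least 2 estimates to compute metrics")
    mean = float(est.mean())
    emp_se = float(est.std(ddof=1))
    sq_err = (est - estimand) ** 2
    mse = float(sq_err.mean())
    sqrt_mse = math.sqrt(mse)
    pct_bias = 100.0 * (mean - estimand) / estimand if estimand != 0 else math.nan

    coverage: Dict[str, float] = {}
    widths: Dict[str, float] = {}
    type2: Dict[str, float] = {}
    type1: Dict[str, float] = {}
    mcse_cov: Dict[str, float] = {}
    fieller_failure = 0.0
    boot_degeneracy = 0.0
    testing_null = estimand == null_value

    for method, ivs in intervals.items():
        if len(ivs) == 0:
            raise ConfigError(f"no intervals recorded for method {method!r}")
        defined = [iv for iv in ivs if iv.defined]
        undefined_rate = 100.0 * (len(ivs) - len(defined)) / len(ivs)
        if method == "fieller":
            fieller_failure = undefined_rate
        if method == "bootstrap" and bootstrap_b is not None:
            short = sum(1 for iv in ivs if (iv.effective_b or 0) < bootstrap_b)
            boot_degeneracy = 100.0 * short / len(ivs)
        if not defined or undefined_rate > FIELLER_SUPPRESSION_THRESHOLD:
            coverage[method] = math.nan
            widths[method] = math.nan
            type2[method] = math.nan
            type1[method] = math.nan
            mcse_cov[method] = math.nan
            continue
        cov = sum(iv.contains(estimand) for iv in defined) / len(defined)
        coverage[method] = 100.0 * cov
        widths[method] = float(np.mean([iv.width for iv in defined]))
        mcse_cov[method] = 100.0 * math.sqrt(cov * (1.0 - cov) / len(defined))
        contains_null = sum(iv.contains(null_value) for iv in defined) / len(defined)
        if testing_null:
            type1[method] = 100.0 * (1.0 - contains_null)
            type2[method] = math.nan
        else:
            type2[method] = 100.0 * contains_null
            type1[method] = math.nan

    return PerformanceSummary(
        percentage_bias=pct_bias,
        emp_se=emp_se,
        sqrt_mse=sqrt_mse,
        coverage=coverage,
        avg_ci_width=widths,
        type2_error=type2,
        type1_error=type1 if testing_null else None,
        fieller_failure_rate=fieller_failure,
        bootstrap_degeneracy_rate=boot_degeneracy,
        mcse_bias=emp_se / math.sqrt(n),
        mcse_emp_se=emp_se / math.sqrt(2.0 * (n - 1)),
        mcse_mse=float(sq_err.std(ddof=1)) / math.sqrt(n),
        mcse_coverage=mcse_cov,
        n_reps=n,
        estimand=estimand,
        mean_estimate=mean,
    )


# ---------------------------------------------------------------------------
# single-dataset pipeline (shared by the engine and the CLI)


def correct_trial(
    trial: TrialDataset,
    calib: CalibrationDataset,
    structure: str,
    ci_methods: Sequence[str] = ("delta",),
    alpha: float = 0.05,
    bootstrap_b: int = 999,
    rng: Optional[np.random.Generator] = None,
):
    """Full corrected analysis of one trial + calibration sample.

    Returns ``(naive_fit, corrected_estimate, calibration_fits)`` where
    ``calibration_fits`` is a single fit (systematic) or an arm pair
    (differential).  Requested intervals are attached to
    ``corrected_estimate.intervals``.
    """
    if structure not in ("systematic", "differential"):
        raise ConfigError(f"unknown correction structure {structure!r}")
    fit = fit_ols(trial.y_star, trial.x)
    if structure == "differential":
        hc3_vcov(fit, trial.y_star, trial.x)
        calibs = fit_calibration_by_arm(calib)
        est = correct_differential(fit, *calibs)
    else:
        calibs = fit_calibration(calib)
        est = correct_systematic(fit, calibs)
    est.alpha_level = alpha
    for method in ci_methods:
        if method == "zero_variance":
            est.intervals[method] = ci_zero_variance(est, fit, calibs, alpha)
        elif method == "delta":
            est.intervals[method] = ci_delta(est, fit, calibs, alpha)
        elif method == "fieller":
            if structure != "systematic":
                raise ConfigError("the Fieller interval applies to systematic error only")
            est.intervals[method] = ci_fieller(fit, calibs, alpha)
        elif method == "bootstrap":
            if rng is None:
                raise ConfigError("bootstrap interval requires a random generator")
            est.intervals[method] = ci_bootstrap(
                trial, calib, structure, bootstrap_b, alpha, rng
            )
        else:
            raise ConfigError(f"unknown ci method {method!r}")
    return fit, est, calibs


def _rep_rng(seed: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(rep,)))


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Run one Monte-Carlo scenario and summarise naive + corrected analyses.

    Per-replication estimator failures (singular calibration, exactly-zero
    slope, fully degenerate bootstrap) are counted and the replication's
    corrected analysis skipped; they are never fatal.
    """
    model = config.outcome_model
    error = config.error_model
    structure = "differential" if error.kind == "differential" else "systematic"
    robust_naive = error.kind in ("differential", "heteroscedastic")
    do_correct = config.k_calibration > 0

    naive_betas: List[float] = []
    naive_ivs: List[IntervalResult] = []
    corr_betas: List[float] = []
    corr_ivs: Dict[str, List[IntervalResult]] = {m: [] for m in config.ci_methods}
    n_failed = 0

    for rep in range(config.n_reps):
        rng = _rep_rng(config.seed, rep)
        trial = generate_trial(model, config.n_per_arm, rng)
        trial = apply_error(trial, error, rng)
        fit = fit_ols(trial.y_star, trial.x)
        if robust_naive:
            hc3_vcov(fit, trial.y_star, trial.x)
        naive_betas.append(fit.beta_star)
        naive_ivs.append(naive_wald_interval(fit, config.alpha, robust=robust_naive))

        if not do_correct:
            continue
        calib = generate_calibration(
            model, error, config.k_calibration, config.calibration_design, rng
        )
        try:
            _, est, _ = correct_trial(
                trial,
                calib,
                structure,
                ci_methods=config.ci_methods,
                alpha=config.alpha,
                bootstrap_b=config.bootstrap_b,
                rng=rng,
            )
        except (SingularCalibrationError, UndefinedCorrectionError, BootstrapFailureError):
            n_failed += 1
            continue
        corr_betas.append(est.beta_hat)
        for m in config.ci_methods:
            corr_ivs[m].append(est.intervals[m])

    estimand = model.beta_y
    naive_summary = compute_metrics(
        naive_betas, {"naive": naive_ivs}, estimand, null_value=0.0
    )
    corrected_summary = None
    if do_correct and len(corr_betas) >= 2:
        corrected_summary = compute_metrics(
            corr_betas,
            corr_ivs,
            estimand,
            null_value=0.0,
            bootstrap_b=config.bootstrap_b,
        )
    return ScenarioResult(
        naive=naive_summary, corrected=corrected_summary, n_failed_corrections=n_failed
    )


# ---------------------------------------------------------------------------
# prognostic-factor experiment


@dataclass
class PrognosticResult:
    """Unadjusted vs covariate-conditional analysis of the same replications."""

    mean_naive: float
    mean_conditional: float
    var_naive: float
    var_conditional: float
    n_reps: int


def run_prognostic_experiment(config: ScenarioConfig) -> PrognosticResult:
    """Compare the unadjusted and prognostic-factor-adjusted naive analyses.

    Each replication fits the regression of the observed endpoint on
    treatment alone and on treatment plus the prognostic factor; reported
    are the mean estimate and the between-replication variance of each.
    """
    model = config.outcome_model
    if model.covariate_prevalence <= 0 and model.covariate_effect == 0:
        raise ConfigError(
            "prognostic experiment requires a prognostic factor "
            "(covariate_prevalence > 0 or covariate_effect != 0)"
        )
    error = config.error_model
    naive = np.empty(config.n_reps)
    conditional = np.empty(config.n_reps)
    for rep in range(config.n_reps):
        rng = _rep_rng(config.seed, rep)
        trial = generate_trial(model, config.n_per_arm, rng)
        trial = apply_error(trial, error, rng)
        naive[rep] = fit_ols(trial.y_star, trial.x).beta_star
        conditional[rep] = fit_ols_adjusted(trial.y_star, trial.x, trial.s).beta_x
    return PrognosticResult(
        mean_naive=float(naive.mean()),
        mean_conditional=float(conditional.mean()),
        var_naive=float(naive.var(ddof=1)),
        var_conditional=float(conditional.var(ddof=1)),
        n_reps=config.n_reps,
    )


# ---------------------------------------------------------------------------
# presets: the published simulation grid


def _base_model() -> OutcomeModel:
    return OutcomeModel(alpha_y=120.0, beta_y=6.9, sigma=12.6)


SYSTEMATIC_K_GRID = (5, 7, 10, 15, 20, 30, 40, 50)
DIFFERENTIAL_K_GRID = (10, 20, 30, 40, 50)
TABLE1_ROWS = ((1.25, 0.8), (1.05, 0.8), (1.05, 0.5), (1.05, 0.2))  # (theta1, R^2)
TABLE2_R2 = (0.8, 0.5, 0.2)


def preset_scenarios(n_reps: int = 10_000, seed: int = 0) -> Dict[str, ScenarioConfig]:
    """The published scenario grid, keyed by a descriptive name.

    Includes: the illustrative small-trial experiments (54 per arm), the
    systematic-error grid (theta1 in {1.05, 1.25} x R^2 in {0.8, 0.5, 0.2} x
    K in {5..50}), the differential grid (R^2 x K in {10..50}), the
    prognostic-factor scenario, and null-effect variants for Type-I checks.
    """
    model = _base_model()
    sigma = model.sigma
    out: Dict[str, ScenarioConfig] = {}

    # --- illustrative small-trial experiments (54 per arm, literal tau=18.1;
    # the systematic variant keeps the same observed-endpoint SD inflation)
    tau_ill = 18.1
    tau_ill_sys = math.sqrt(22.05**2 - (1.05 * sigma) ** 2)
    out["sec21_classical"] = ScenarioConfig(
        outcome_model=model,
        error_model=ErrorModel.classical(tau_ill),
        n_per_arm=54,
        k_calibration=0,
        n_reps=n_reps,
        seed=seed,
    )
    out["sec21_systematic"] = ScenarioConfig(
        outcome_model=model,
        error_model=ErrorModel.systematic(0.0, 1.05, tau_ill_sys),
        n_per_arm=54,
        k_calibration=0,
        n_reps=n_reps,
        seed=seed,
    )
    out["sec21_differential"] = ScenarioConfig(
        outcome_model=model,
        error_model=ErrorModel.differential(0.0, 0.0, 1.0, 1.05, tau_ill, tau_ill_sys),
        n_per_arm=54,
        k_calibration=0,
        n_reps=n_reps,
        seed=seed,
    )

    # --- systematic-error grid
    sys_methods = ("zero_variance", "delta", "fieller", "bootstrap")
    for theta1, r2 in TABLE1_ROWS:
        tau = tau_for_r2(theta1, sigma, r2)
        for k in SYSTEMATIC_K_GRID:
            name = f"table1_r{int(round(r2 * 10)):02d}_t{int(theta1 * 100)}_k{k}"
            out[name] = ScenarioConfig(
                outcome_model=model,
                error_model=ErrorModel.systematic(0.0, theta1, tau),
                n_per_arm=200,
                k_calibration=k,
                calibration_design="placebo_only",
                n_reps=n_reps,
                ci_methods=sys_methods,
                seed=seed,
            )

    # --- differential-error grid
    diff_methods = ("zero_variance", "delta", "bootstrap")
    for r2 in TABLE2_R2:
        tau0 = tau_for_r2(1.0, sigma, r2)
        tau1 = tau_for_r2(1.05, sigma, r2)
        for k in DIFFERENTIAL_K_GRID:
            name = f"table2_r{int(round(r2 * 10)):02d}_k{k}"
            out[name] = ScenarioConfig(
                outcome_model=model,
                error_model=ErrorModel.differential(0.0, 0.0, 1.0, 1.05, tau0, tau1),
                n_per_arm=200,
                k_calibration=k,
                calibration_design="two_arm",
                n_reps=n_reps,
                ci_methods=diff_methods,
                seed=seed,
            )

    # --- prognostic-factor experiment
    out["sec54_prognostic"] = ScenarioConfig(
        outcome_model=OutcomeModel(
            alpha_y=120.0,
            beta_y=6.9,
            sigma=12.6,
            covariate_effect=10.0,
            covariate_prevalence=0.75,
        ),
        error_model=ErrorModel.covariate_additive(covariate_shift=0.5, tau=6.6),
        n_per_arm=200,
        k_calibration=0,
        n_reps=n_reps,
        seed=seed,
    )

    # --- null-effect variants (Type-I checks)
    null_model = OutcomeModel(alpha_y=120.0, beta_y=0.0, sigma=12.6)
    out["null_systematic_r08"] = ScenarioConfig(
        outcome_model=null_model,
        error_model=ErrorModel.systematic(0.0, 1.05, tau_for_r2(1.05, sigma, 0.8)),
        n_per_arm=200,
        k_calibration=0,
        n_reps=n_reps,
        seed=seed,
    )
    out["null_differential_r08"] = ScenarioConfig(
        outcome_model=null_model,
        error_model=ErrorModel.differential(
            0.0, 0.0, 1.0, 1.05, tau_for_r2(1.0, sigma, 0.8), tau_for_r2(1.05, sigma, 0.8)
        ),
        n_per_arm=200,
        k_calibration=0,
        n_reps=n_reps,
        seed=seed,
    )
    return out
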