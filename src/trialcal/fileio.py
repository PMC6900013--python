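"""CSV/YAML/JSON readers and writers, configuration validation, manifests.

CSV dialect: comma-separated, UTF-8, "." decimal separator, header row
mandatory, no missing values (endpoint data with missingness is out of
scope).  All validation problems in a file or a configuration are collected
and reported together, with row numbers where applicable (row 1 is the
first data row after the header).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datagen import CalibrationDataset, ErrorModel, OutcomeModel, TrialDataset
from .errors import ConfigError, DataValidationError
from .simulation import ScenarioConfig

__all__ = [
    "read_trial_csv",
    "write_trial_csv",
    "read_calibration_csv",
    "write_calibration_csv",
    "validate_config",
    "load_config",
    "config_to_dict",
    "RunManifest",
]

logger = logging.getLogger("trialcal")


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"file not found: {path}")
    # round_trip float parsing: written values must read back bit-exactly
    frame = pd.read_csv(path, float_precision="round_trip")
    return frame


def _check_binary(frame: pd.DataFrame, col: str, problems: List[str]) -> None:
    bad = frame.index[~frame[col].isin((0, 1))]
    for i in bad:
        problems.append(f"row {i + 1}: {col} must be 0 or 1, got {frame[col].iloc[i]!r}")


def _check_missing(frame: pd.DataFrame, problems: List[str]) -> None:
    for col in frame.columns:
        missing = frame.index[frame[col].isna()]
        for i in missing:
            problems.append(f"row {i + 1}: missing value in column {col!r}")


def read_trial_csv(path) -> TrialDataset:
    """Read participant-level trial data (columns x, y_star[, y_true][, s])."""
    frame = _read_csv(path)
    problems: List[str] = []
    for col in ("x", "y_star"):
        if col not in frame.columns:
            problems.append(f"missing required column {col!r}")
    if problems:
        raise DataValidationError(problems)
    _check_missing(frame, problems)
    if not problems:
        _check_binary(frame, "x", problems)
        if "s" in frame.columns:
            _check_binary(frame, "s", problems)
        for arm in (0, 1):
            if int((frame["x"] == arm).sum()) < 2:
                problems.append(f"fewer than 2 participants in arm {arm}")
    if problems:
        raise DataValidationError(problems)
    return TrialDataset(
        x=frame["x"].to_numpy(),
        y_star=frame["y_star"].to_numpy(dtype=float),
        y_true=frame["y_true"].to_numpy(dtype=float) if "y_true" in frame.columns else None,
        s=frame["s"].to_numpy() if "s" in frame.columns else None,
    )


def write_trial_csv(trial: TrialDataset, path) -> None:
    data: Dict[str, Any] = {"x": trial.x}
    if trial.y_star is not None:
        data["y_star"] = trial.y_star
    if trial.y_true is not None:
        data["y_true"] = trial.y_true
    if trial.s is not None:
        data["s"] = trial.s
    pd.DataFrame(data).to_csv(path, index=False)


def read_calibration_csv(path) -> CalibrationDataset:
    """Read a calibration sample (columns y_true, y_star[, x]).

    A constant ``y_true`` column draws an early warning: the calibration
    regression will be singular downstream.
    """
    frame = _read_csv(path)
    problems: List[str] = []
    for col in ("y_true", "y_star"):
        if col not in frame.columns:
            problems.append(f"missing required column {col!r}")
    if problems:
        raise DataValidationError(problems)
    _check_missing(frame, problems)
    if not problems and "x" in frame.columns:
        _check_binary(frame, "x", problems)
    if problems:
        raise DataValidationError(problems)
    if frame["y_true"].nunique() == 1:
        logger.warning(
            "calibration file %s: y_true is constant; the calibration regression "
            "will be singular",
            path,
        )
    return CalibrationDataset(
        y_true=frame["y_true"].to_numpy(dtype=float),
        y_star=frame["y_star"].to_numpy(dtype=float),
        x=frame["x"].to_numpy() if "x" in frame.columns else None,
    )


def write_calibration_csv(calib: CalibrationDataset, path) -> None:
    data: Dict[str, Any] = {"y_true": calib.y_true, "y_star": calib.y_star}
    if calib.x is not None:
        data["x"] = calib.x
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# scenario configuration

_OUTCOME_KEYS = {"alpha_y", "beta_y", "sigma", "covariate_effect", "covariate_prevalence"}
_ERROR_KEYS = {
    "kind",
    "theta0",
    "theta1",
    "tau",
    "theta00",
    "theta01",
    "theta10",
    "theta11",
    "tau0",
    "tau1",
    "covariate_shift",
}
_TOP_KEYS = {
    "outcome_model",
    "error_model",
    "n_per_arm",
    "k_calibration",
    "calibration_design",
    "n_reps",
    "ci_methods",
    "alpha",
    "bootstrap_b",
    "seed",
}


def validate_config(raw: Mapping[str, Any]) -> ScenarioConfig:
    """Type-check, default and cross-validate a raw scenario mapping.

    All problems are collected and raised together as a single
    :class:`~trialcal.errors.ConfigError`.
    """
    problems: List[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        problems.append(f"unknown keys: {sorted(unknown)}")
    for section, allowed in (("outcome_model", _OUTCOME_KEYS), ("error_model", _ERROR_KEYS)):
        sub = raw.get(section)
        if not isinstance(sub, Mapping):
            problems.append(f"{section} must be a mapping")
            continue
        bad = set(sub) - allowed
        if bad:
            problems.append(f"{section}: unknown keys: {sorted(bad)}")
    for key in ("n_per_arm", "k_calibration"):
        if key not in raw:
            problems.append(f"missing required key {key!r}")
    if problems:
        raise ConfigError(problems)

    try:
        outcome = OutcomeModel(**raw["outcome_model"])
    except (TypeError, ValueError) as exc:
        problems.append(f"outcome_model: {exc}")
        outcome = None
    try:
        error = ErrorModel(**raw["error_model"])
    except (TypeError, ValueError) as exc:
        problems.append(f"error_model: {exc}")
        error = None
    if problems:
        raise ConfigError(problems)

    kwargs: Dict[str, Any] = {
        "outcome_model": outcome,
        "error_model": error,
        "n_per_arm": int(raw["n_per_arm"]),
        "k_calibration": int(raw["k_calibration"]),
    }
    if "calibration_design" in raw:
        kwargs["calibration_design"] = str(raw["calibration_design"])
    elif error.kind == "differential":
        kwargs["calibration_design"] = "two_arm"
    if "n_reps" in raw:
        kwargs["n_reps"] = int(raw["n_reps"])
    if "ci_methods" in raw:
        kwargs["ci_methods"] = tuple(raw["ci_methods"])
    if "alpha" in raw:
        kwargs["alpha"] = float(raw["alpha"])
    if "bootstrap_b" in raw:
        kwargs["bootstrap_b"] = int(raw["bootstrap_b"])
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    return ScenarioConfig(**kwargs)  # ScenarioConfig collects its own problems


def load_config(path) -> ScenarioConfig:
    """Load a scenario configuration from a YAML (or JSON) file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"configuration file {path} does not contain a mapping")
    return validate_config(raw)


def config_to_dict(config: ScenarioConfig) -> Dict[str, Any]:
    """Round-trippable plain-dict form of a scenario configuration."""
    out = dataclasses.asdict(config)
    out["outcome_model"] = dataclasses.asdict(config.outcome_model)
    out["error_model"] = {
        k: v for k, v in dataclasses.asdict(config.error_model).items() if v is not None
    }
    out["ci_methods"] = list(config.ci_methods)
    return out


# ---------------------------------------------------------------------------
# run manifests


@dataclass
class RunManifest:
    """Provenance record emitted alongside every CLI output.

    Any output can be regenerated bit-identically from the recorded
    configuration and seed.
    """

    command: str
    config_hash: str
    seed: int
    version: str
    timestamp: str
    failure_counts: Dict[str, int]

    @classmethod
    def create(
        cls,
        command: str,
        config: Mapping[str, Any],
        seed: int,
        failure_counts: Optional[Dict[str, int]] = None,
    ) -> "RunManifest":
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()
        return cls(
            command=command,
            config_hash=digest,
            seed=seed,
            version=__version__,
            timestamp=datetime.now(timezone.utc).isoformat(),
            failure_counts=failure_counts or {},
        )

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)
            fh.write("\n")
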