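"""Exception hierarchy for trialcal.

All package exceptions derive from :class:`TrialcalError` so callers can catch
everything with one clause; the simulation engine additionally distinguishes
per-replication estimator failures (counted, never fatal) by type.
"""


class TrialcalError(Exception):
    """Base class for all trialcal errors."""


class InvalidModelError(TrialcalError, ValueError):
    """An outcome or error model violates its parameter constraints."""


class DataValidationError(TrialcalError, ValueError):
    """One or more dataset validation failures; all messages are collected."""

    def __init__(self, messages):
        if isinstance(messages, str):
            messages = [messages]
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


class SingularDesignError(TrialcalError, ValueError):
    """The trial design matrix is singular (e.g. constant treatment column)."""


class DegenerateDesignError(SingularDesignError):
    """A design with leverage one (an arm of size one); HC3 is undefined."""


class SingularCalibrationError(TrialcalError, ValueError):
    """Calibration regression undefined (constant error-free endpoint)."""


class UndefinedCorrectionError(TrialcalError, ArithmeticError):
    """Corrected estimator undefined (estimated calibration slope exactly zero)."""


class BootstrapFailureError(TrialcalError, RuntimeError):
    """All bootstrap resamples were degenerate; no interval can be formed."""


class ConfigError(TrialcalError, ValueError):
    """Scenario configuration invalid; all problems are collected."""

    def __init__(self, messages):
        if isinstance(messages, str):
            messages = [messages]
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))
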