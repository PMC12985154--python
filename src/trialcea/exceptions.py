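"""Exception hierarchy for trialcea."""


class TrialCEAError(Exception):
    """Base class for all package errors."""


class ValidationError(TrialCEAError, ValueError):
    """Invalid data value (out-of-range level, utility, hours, ...)."""


class ConfigurationError(TrialCEAError, ValueError):
    """Invalid configuration (bad probability, missing stratum, bad rate, ...)."""


class EstimationError(TrialCEAError, RuntimeError):
    """Degenerate design or insufficient data for an estimate."""


class ImputationError(TrialCEAError, RuntimeError):
    """Multiple imputation cannot proceed (e.g. a fully missing column)."""


class LoadError(TrialCEAError, ValueError):
    """Input table or config file violates its schema."""
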