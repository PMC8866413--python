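"""Exception hierarchy for coxrisk."""


class CoxRiskError(Exception):
    """Base class for all coxrisk errors."""


class ConfigError(CoxRiskError):
    """Invalid generator or pipeline configuration."""


class SchemaError(CoxRiskError):
    """Cohort table violates the declared schema."""


class FitError(CoxRiskError):
    """A survival model could not be fitted (degenerate design, no events,
    non-convergence)."""


class ModelIOError(CoxRiskError):
    """A risk-model bundle could not be read or has an unsupported version."""
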