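"""Exception hierarchy for the msmediation package."""


class MsmediationError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MsmediationError, ValueError):
    """An invalid generator or analysis parameter (names the offending field)."""


class CodingError(MsmediationError, ValueError):
    """A raw score outside its declared scale range."""


class EligibilityError(MsmediationError):
    """Eligibility filtering removed every subject."""


class CohortValidationError(MsmediationError, ValueError):
    """A cohort table violates a structural invariant (range, monotone censoring...)."""


class FittingError(MsmediationError):
    """A probability or outcome model failed to converge or separated perfectly."""


class DataError(MsmediationError):
    """An at-risk set or analysis set is empty or too small to fit on."""


class PositivityError(MsmediationError):
    """A denominator model assigned probability zero to an observed state."""


class ConsistencyError(MsmediationError):
    """A subject in the analysis set is missing a required component or value."""


class DegenerateEstimandError(MsmediationError):
    """A causal contrast is undefined (zero risk in the reference arm)."""


class DegenerateFitError(MsmediationError):
    """The outcome is constant, so the regression is degenerate."""


class ImputationError(MsmediationError):
    """Chained-equations imputation cannot proceed (e.g. a fully missing column)."""


class BootstrapError(MsmediationError):
    """Too many bootstrap replicates failed to produce an estimate."""


class UnsupportedScenarioError(MsmediationError):
    """A sensitivity scenario is not defined for the requested analysis mode."""
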