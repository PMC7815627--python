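"""Exception hierarchy for cohort I/O, classification and model fitting."""


class IldtrajError(Exception):
    """Base class for all package errors."""


class SchemaError(IldtrajError):
    """A required column is missing or a value has the wrong type."""


class IntegrityError(IldtrajError):
    """Row-level invariant violated (duplicate visits, unknown patient ids...)."""


class DomainError(IldtrajError):
    """An operation was called outside its domain (non-finite delta, empty input)."""


class ConfigError(IldtrajError):
    """Invalid simulation or threshold configuration."""


class FeasibilityError(IldtrajError):
    """A requested fixture cell cannot be realised by any trajectory."""


class ConvergenceError(IldtrajError):
    """A model fit failed to converge (e.g. complete separation in logistic regression)."""
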