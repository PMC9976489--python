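"""Exception hierarchy shared across the package."""


class MethclockError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MethclockError):
    """A delimited file does not have the expected layout."""


class ValidationError(MethclockError):
    """Values violate a documented invariant (range, duplicates, rank)."""


class ImputationError(MethclockError):
    """A (cohort, CpG) group has no observed values to impute from."""


class ConfigError(MethclockError):
    """A configuration field is missing or out of range."""


class ConvergenceError(MethclockError):
    """An iterative fit failed to converge and no fallback applies."""
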