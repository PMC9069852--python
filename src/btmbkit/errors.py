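"""Exception hierarchy shared across the package."""


class BtmbkitError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(BtmbkitError):
    """Input data violates a documented contract (bad value, bad row, bad id)."""


class ConfigurationError(BtmbkitError):
    """A configuration value is out of range, unknown, or inconsistent."""


class DegenerateLabelsError(ValidationError):
    """Binary labels contain only one class; ROC/AUC quantities are undefined."""


class ConvergenceError(BtmbkitError):
    """An iterative fit failed to converge (e.g. monotone Cox partial likelihood)."""


class EmptyInputError(ValidationError):
    """An operation that requires at least one observation received none."""
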