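"""Exception hierarchy shared across the package.

The command-line layer maps these onto distinct exit codes, so code deeper
in the library should raise the most specific class that applies.
"""


class DTNIError(Exception):
    """Base class for all package-specific errors."""


class FormatError(DTNIError):
    """A file does not conform to the expected dialect (missing columns,
    malformed lines, non-numeric values)."""


class DataValidationError(DTNIError):
    """Input data violate a structural requirement (unbalanced design,
    empty gene intersection, too few doses or time points)."""


class InferenceError(DTNIError):
    """The estimation step cannot proceed (underdetermined system for the
    requested estimator, too few observations)."""


class ConfigError(DTNIError):
    """A pipeline configuration file is invalid or references missing
    resources."""
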