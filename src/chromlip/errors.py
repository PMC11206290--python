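"""Exception hierarchy shared across the package."""


class ChromlipError(Exception):
    """Base class for every error raised by chromlip."""


class SchemaError(ChromlipError):
    """An input table is missing a required column or has a malformed header."""


class ValidationError(ChromlipError):
    """Row values violate a domain invariant (e.g. R_F outside (0, 1))."""


class InsufficientDesignError(ChromlipError):
    """Too few distinct design points to fit the requested model."""


class DegenerateDesignError(ChromlipError):
    """The predictor has zero variance; the regression is undefined."""


class UndefinedValueError(ChromlipError):
    """A derived quantity is undefined for the given inputs (e.g. C0 with b = 0)."""


class AlignmentError(ChromlipError):
    """Two series do not share the identifiers required to pair them."""


class DescriptorLookupError(ChromlipError):
    """A requested descriptor/series name is not present in the data bundle."""


class ConfigurationError(ChromlipError):
    """A required configuration value (e.g. a rule threshold) is missing."""


class IncompleteRowError(ChromlipError):
    """A matrix row has missing cells where a complete row is required."""
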