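"""Exception types raised across the package."""


class FBAMError(ValueError):
    """Base class for all package-specific errors."""


class InvalidPartitionError(FBAMError):
    """A band partition violates the cut-ordering or minimum-width rules."""


class DegenerateInputError(FBAMError):
    """Input data cannot be processed (e.g. a constant series under standardization)."""


class DegenerateCriterionError(FBAMError):
    """A similarity ratio has a zero denominator on this data."""


class UndefinedCriterionError(FBAMError):
    """A criterion is undefined for this (J, L), e.g. band similarity at L = 1."""


class SelectionError(FBAMError):
    """No grid entry admits the requested model selection."""
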