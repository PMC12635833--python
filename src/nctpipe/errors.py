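"""Exception hierarchy shared across the pipeline."""


class NctPipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(NctPipeError):
    """A parameter or option is inconsistent with the data or another option."""


class ValidationError(NctPipeError):
    """An input matrix or table violates a structural invariant."""


class EstimationError(NctPipeError):
    """A statistical estimate is undefined for the given data."""


class DegenerateInputError(NctPipeError):
    """The input is a degenerate case for which the operation is undefined."""


class StabilityError(NctPipeError):
    """A system matrix does not satisfy the stability requirement."""


class NumericError(NctPipeError):
    """A numerical routine failed to converge or produced invalid output."""
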