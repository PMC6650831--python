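"""Exception and warning types shared across the package."""


class LepnlmError(Exception):
    """Base class for all package errors."""


class ConfigurationError(LepnlmError, ValueError):
    """A parameter value violates its contract (negative sigma, even window, ...)."""


class InputError(LepnlmError, ValueError):
    """An input array violates a precondition (wrong shape, too small, ...)."""


class DegenerateInputError(InputError):
    """The input is formally valid but carries no usable information
    (e.g. a constant image handed to a histogram thresholder)."""


class UnreliableEstimateWarning(UserWarning):
    """Raised when an estimate is returned but its support is too small to trust."""
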