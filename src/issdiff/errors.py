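"""Exception hierarchy shared by all issdiff modules."""


class IssdiffError(Exception):
    """Base class for all package errors."""


class InvalidInputError(IssdiffError, ValueError):
    """An argument violates a documented precondition or invariant."""


class NumericalError(IssdiffError, RuntimeError):
    """A numerical routine failed to reach its requested accuracy.

    Attributes
    ----------
    achieved_tolerance : float or None
        The relative tolerance the routine actually reached, when known.
    """

    def __init__(self, message: str, achieved_tolerance: float | None = None):
        super().__init__(message)
        self.achieved_tolerance = achieved_tolerance


class InsufficientDataError(IssdiffError, ValueError):
    """Fewer usable samples than the estimation procedure requires."""


class FormatError(IssdiffError, ValueError):
    """A file on disk does not conform to the expected schema."""


class ConfigError(IssdiffError, ValueError):
    """Run configuration failed validation; message enumerates all violations."""
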