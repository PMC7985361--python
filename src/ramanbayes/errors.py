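"""Exception types shared across the package."""


class RamanBayesError(Exception):
    """Base class for all package errors."""


class ValidationError(RamanBayesError, ValueError):
    """An input violates a documented precondition or invariant."""


class IngestionError(RamanBayesError, IOError):
    """A manifest row or spectrum file could not be read."""


class ConvergenceWarning(UserWarning):
    """An iterative solver stopped at its iteration cap."""
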