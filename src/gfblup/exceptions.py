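"""Exception hierarchy shared across the package."""


class GfblupError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GfblupError):
    """A file on disk is malformed or internally inconsistent."""


class ValidationError(GfblupError):
    """An in-memory object violates one of its invariants."""


class ParameterError(GfblupError, ValueError):
    """A caller-supplied parameter is outside its legal range."""


class LinAlgError(GfblupError):
    """A matrix that the method requires to be invertible/PD is not."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped before meeting its tolerance."""
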