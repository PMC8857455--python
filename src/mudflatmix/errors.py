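"""Exception hierarchy shared across the package."""


class MudflatmixError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MudflatmixError, ValueError):
    """An input record or argument violates a documented invariant."""


class FormatError(MudflatmixError, ValueError):
    """A file on disk does not match the documented table dialect."""


class DomainError(MudflatmixError, ArithmeticError):
    """A computation is undefined for the supplied values (e.g. division
    by a zero protein fraction, coincident mixing endpoints)."""
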