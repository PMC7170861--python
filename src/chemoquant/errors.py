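"""Exception hierarchy.

All errors raised by this package derive from :class:`ChemoquantError` so
callers can catch everything with one clause while tests can pin down the
specific failure mode.
"""


class ChemoquantError(Exception):
    """Base class for all package errors."""


class ParameterError(ChemoquantError, ValueError):
    """A simulation or analysis parameter violates its invariant."""


class InputError(ChemoquantError, ValueError):
    """An input record violates a precondition (too few points, empty, ...)."""


class GeometryError(ChemoquantError, ValueError):
    """A geometric construction is impossible (cell outside grid, ...)."""


class ComputationError(ChemoquantError, ArithmeticError):
    """A metric is undefined for the given data (zero baseline, ...)."""


class FormatError(ChemoquantError, ValueError):
    """A file does not match the expected dialect."""


class ValidationError(ChemoquantError, ValueError):
    """File contents parsed but failed semantic validation."""
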