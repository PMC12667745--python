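"""Exception hierarchy.

Exit-code mapping used by the CLI: user errors (bad flags, bad shapes) are
``InvalidInputError``; data errors (unreadable or inconsistent files) are
``DataError``; numerical failures (singular background, degenerate quadratic
forms) are ``NumericalError``.
"""


class RhoPCAError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RhoPCAError, ValueError):
    """Arguments violate a documented precondition."""


class DataError(RhoPCAError):
    """Input files are unreadable, malformed, or mutually inconsistent."""


class AlignmentError(DataError):
    """Feature names diverge between target and background."""


class EmptySampleError(DataError):
    """Rows with zero total count cannot be depth-normalized."""


class NumericalError(RhoPCAError):
    """A numerical operation failed or is undefined."""


class DegenerateBackgroundError(NumericalError):
    """The background quadratic form v'Sigma_B v is non-positive."""


class SingularBackgroundError(NumericalError):
    """Sigma_B + mu*I is not positive definite; regularization is needed."""
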