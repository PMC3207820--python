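"""Exception hierarchy shared across the package.

Validation problems (bad input data, malformed files, out-of-range
parameters) and numerical failures (non-convergence, degenerate
statistics) are kept distinct so the command-line front end can map
them to different exit codes.
"""


class LumpchainError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LumpchainError, ValueError):
    """Invalid input: bad graph/partition data or parameter values."""


class ParseError(ValidationError):
    """A file could not be parsed in the declared dialect."""


class NumericalError(LumpchainError, RuntimeError):
    """A numerical procedure failed (non-convergence, zero variance, ...)."""
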