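"""Exception hierarchy shared across the package.

The CLI maps :class:`InputError` to exit code 2 and
:class:`ConvergenceError` to exit code 3.
"""


class HemoturbError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class InputError(HemoturbError):
    """Invalid or malformed user input (bad file, bad parameter value)."""

    exit_code = 2


class DegenerateInputError(InputError):
    """Structurally valid input on which the operation is undefined
    (all-zero signal, constant waveform with no unique peak, ...)."""


class StatisticsError(InputError):
    """Not enough independent samples for the requested statistic."""


class ConvergenceError(HemoturbError):
    """An iterative procedure failed to reach its tolerance."""

    exit_code = 3

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
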