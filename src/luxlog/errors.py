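"""Typed exceptions shared across the package.

All errors derive from :class:`LuxlogError` so that batch drivers can
catch analysis failures without swallowing programming errors.
"""


class LuxlogError(Exception):
    """Base class for all luxlog errors."""


class ChannelNotFoundError(LuxlogError, KeyError):
    """Requested channel name does not exist in the recording."""


class IrregularEpochError(LuxlogError, ValueError):
    """Timestamps are not strictly increasing at a constant epoch, or the
    epoch does not divide the folding period."""


class EmptySelectionError(LuxlogError, ValueError):
    """A selection (time window, glob pattern) matched no data."""


class ParseError(LuxlogError, ValueError):
    """A text input could not be parsed; carries file/line context."""

    def __init__(self, message: str, *, path=None, line: int | None = None):
        ctx = []
        if path is not None:
            ctx.append(str(path))
        if line is not None:
            ctx.append(f"line {line}")
        prefix = f"[{': '.join(ctx)}] " if ctx else ""
        super().__init__(prefix + message)
        self.path = path
        self.line = line


class InvalidIntervalError(LuxlogError, ValueError):
    """A mask interval has stop <= start."""


class ResampleIncompatibilityError(LuxlogError, ValueError):
    """Target epoch is not a positive integer multiple of the current one."""


class MissingDataError(LuxlogError, ValueError):
    """Operation requires gap-free data but missing values are present."""


class InvalidFilterError(LuxlogError, ValueError):
    """Filter specification invalid for the series' sampling rate."""


class DomainError(LuxlogError, ValueError):
    """Input values outside the mathematical domain of a transform."""


class ParameterError(LuxlogError, ValueError):
    """Invalid parameter value (unknown enum token, empty metric list, ...)."""


class UndefinedMetricError(LuxlogError, ArithmeticError):
    """Metric is mathematically undefined for this input (e.g. 0/0 on a
    constant series)."""


class InsufficientDataError(LuxlogError, ValueError):
    """Not enough valid data to evaluate the operation (e.g. every candidate
    L5/M10 window contains a missing profile period)."""
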