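"""Exception hierarchy shared across the toolkit.

Every stage raises a subclass of :class:`MethylEditError` so pipeline
drivers can attach a stage label and abort cleanly.
"""


class MethylEditError(Exception):
    """Base class for all toolkit errors."""


class ParameterError(MethylEditError, ValueError):
    """A numeric parameter is outside its documented domain."""


class ConfigurationError(MethylEditError, ValueError):
    """Mutually inconsistent settings (e.g. amplicon shorter than read length)."""


class FormatError(MethylEditError, ValueError):
    """Malformed input record; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CoordinateError(MethylEditError, ValueError):
    """Interval outside chromosome bounds, or degenerate coordinates."""


class DegenerateInputError(MethylEditError, ValueError):
    """Input that makes the operation meaningless (no CpGs, all-equal signal...)."""


class NormalizationError(MethylEditError, ValueError):
    """Scaling impossible (zero fragments, zero reference mean...)."""


class MissingDataError(MethylEditError, ValueError):
    """A required measurement is absent (uncovered analysis CpG, missing sample)."""


class QCNotComputableError(MethylEditError, ValueError):
    """Quality-control statistic undefined for this input."""
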