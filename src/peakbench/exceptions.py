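"""Exception hierarchy for peakbench.

All toolkit errors derive from :class:`PeakBenchError` so callers (and the CLI,
which maps them to exit code 1) can catch one type.
"""


class PeakBenchError(Exception):
    """Base class for all peakbench errors."""


class ValidationError(PeakBenchError):
    """Invalid in-memory data: bad coordinates, non-binary vectors, bad configs."""


class ChromosomeMismatchError(ValidationError):
    """Two intervals on different chromosomes were compared; they are incomparable."""


class ParseError(PeakBenchError):
    """A file could not be parsed; carries the path and 1-based line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix = f"{path}:"
            if line is not None:
                prefix += f"{line}:"
            prefix += " "
        super().__init__(prefix + message)


class MissingSampleError(PeakBenchError):
    """A label references a sample or sample group absent from the scored call set."""


class ThresholdError(PeakBenchError):
    """A threshold not on the call set's grid was requested (no interpolation)."""
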