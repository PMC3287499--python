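"""Exception hierarchy shared by all condegree modules."""


class CondegreeError(Exception):
    """Base class for all condegree-specific errors."""


class ParseError(CondegreeError):
    """A tabular input file could not be parsed (names the offending cell)."""


class ValidationError(CondegreeError):
    """An input violates a container invariant (duplicate ids, bad label, ...)."""


class DegenerateInputError(CondegreeError):
    """Input is formally valid but too degenerate for the requested analysis
    (e.g. fewer than two samples per class, all genes constant)."""


class UndefinedCorrelationError(DegenerateInputError):
    """A correlation was requested for a constant vector."""


class SeriesSizeError(CondegreeError):
    """A change-point series is outside the size range an engine supports."""


class DegenerateSimulationError(CondegreeError):
    """A synthetic-data configuration produced an unusable dataset."""
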