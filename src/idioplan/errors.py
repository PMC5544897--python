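"""Exception hierarchy for the planning and monitoring pipeline."""


class IdioplanError(Exception):
    """Base class for all package-specific errors."""


class FormatError(IdioplanError):
    """Malformed input file: missing columns, unparsable timestamps."""


class ValidationError(IdioplanError):
    """Input violates a declared invariant (e.g. out-of-scale value)."""


class UnrecoverableSeriesError(IdioplanError):
    """An item has too few observed points to be cleaned or modelled."""


class InvalidWindowError(IdioplanError):
    """A time window or moving window is degenerate (sleep <= wake, m > T)."""


class ConvergenceError(IdioplanError):
    """An iterative fit failed to converge within its iteration budget."""


class UnidentifiedModelError(IdioplanError):
    """Model has non-positive degrees of freedom or an under-identified pattern."""


class SampleSizeError(IdioplanError):
    """Too few observations for the requested model."""


class CollinearityError(IdioplanError):
    """Singular regressor matrix in a least-squares fit."""


class DegenerateScoresError(IdioplanError):
    """All factor products or item means are zero; priorities undefined."""


class InsufficientDataError(IdioplanError):
    """Series shorter than the configured minimum number of measurements."""
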