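"""Exception hierarchy shared across the package."""


class FecgError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FecgError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(FecgError, ValueError):
    """A file or in-memory structure violates its format contract."""


class ParseError(FormatError):
    """Text input could not be parsed; message carries location info."""


class SegmentationError(FecgError, ValueError):
    """Beat segmentation is impossible for the given R peaks/windows."""


class EstimationError(FecgError, ValueError):
    """Too little data to estimate a template or statistic."""


class ExtractionError(FecgError, RuntimeError):
    """A stage of an extraction cascade failed."""


class MetricError(FecgError, ValueError):
    """A metric's precondition is not met (e.g. zero variance)."""
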