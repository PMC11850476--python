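"""Exception types raised by the pipeline.

All are ValueError/RuntimeError subclasses so callers that do not care about
the fine distinction can catch the built-ins.
"""


class DimensionalityError(ValueError):
    """Input raster is not a 2-D single-channel image."""


class AlignmentError(ValueError):
    """A mask does not match the shape of its frame."""


class FormatError(ValueError):
    """A file holds values incompatible with the expected format."""


class ConsistencyError(ValueError):
    """Inputs contradict each other (mixed times, duplicate time points...)."""


class InsufficientDataError(ValueError):
    """Not enough observations to compute the requested statistic."""


class NormalizationError(ValueError):
    """A baseline value is missing or zero, so ratios are undefined."""


class TimeParseError(ValueError):
    """Acquisition time could not be parsed from a filename."""


class CapacityError(RuntimeError):
    """A simulated scene cannot accommodate the requested objects."""
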