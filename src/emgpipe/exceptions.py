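"""Exception hierarchy shared across the pipeline stages."""


class EmgPipeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EmgPipeError):
    """A parameter combination is invalid (e.g. band edge at/above Nyquist)."""


class EmptyRecordingError(ConfigurationError):
    """All class counts are zero: nothing to generate."""


class FormatError(EmgPipeError):
    """An on-disk artifact is malformed; the message names the offending line."""


class DegenerateInputError(EmgPipeError):
    """Input admits no defined result (e.g. z-scoring a constant signal)."""


class SegmentationError(EmgPipeError):
    """An event cannot be segmented (too close to a recording edge)."""


class ShapeError(EmgPipeError):
    """Array dimensions do not agree across inputs."""


class UndefinedMetricError(EmgPipeError):
    """A metric is undefined for the given fold (e.g. single-class AUC)."""
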