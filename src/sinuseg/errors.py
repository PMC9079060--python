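"""Exception hierarchy for sinuseg.

All package-specific failures derive from :class:`SinusegError` so callers
(and the CLI) can distinguish domain errors from programming errors.
"""


class SinusegError(Exception):
    """Base class for all sinuseg errors."""


class FormatError(SinusegError):
    """A file or file series violates its format contract (e.g. a DICOM
    series with inconsistent orientation)."""


class GeometryError(SinusegError):
    """A geometric precondition is violated (cavity outside the grid,
    patch larger than the volume, ...)."""


class ShapeError(SinusegError):
    """An array shape does not satisfy an operation's contract."""


class MetricError(SinusegError):
    """A metric is undefined for the given inputs (e.g. empty surface)."""


class ConfigError(SinusegError):
    """Invalid or inconsistent configuration."""


class TrainingError(SinusegError):
    """Training diverged or could not proceed (e.g. non-finite loss)."""


class EmptyPredictionError(SinusegError):
    """The pipeline produced an empty mask (clinical class E: the model
    could not predict anything)."""
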