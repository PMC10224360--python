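"""Exception hierarchy.

Every user-facing failure mode gets a distinct, named exception so callers
(and the CLI) can distinguish validation problems from computation problems.
"""


class ElectromeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ElectromeError, ValueError):
    """An invalid field in a generator or pipeline configuration.

    The message names the offending field.
    """


class SignalIOError(ElectromeError):
    """Base class for recording/band file problems."""


class MissingSidecarError(SignalIOError, FileNotFoundError):
    """Recording CSV present but its ``<stem>.meta.json`` sidecar is not."""


class NonFiniteValueError(SignalIOError, ValueError):
    """A voltage sample is NaN or infinite."""


class NonMonotoneTimeError(SignalIOError, ValueError):
    """The time column of a recording CSV is not strictly increasing."""


class SamplingRateMismatchError(SignalIOError, ValueError):
    """Sidecar sampling rate disagrees with the file's median time step."""


class BandDefinitionError(ElectromeError, ValueError):
    """Malformed band definition (empty interval, negative edge, duplicate name)."""


class EmptyBandError(ElectromeError, ValueError):
    """A requested band lies entirely above the Nyquist frequency."""


class UndefinedCentroidError(ElectromeError, ValueError):
    """Spectral centroid requested for a window with zero total power."""


class ShortRecordingError(ElectromeError, ValueError):
    """Recording too short for the requested segmentation or PSD window."""


class CohortMismatchError(ElectromeError, ValueError):
    """Feature series being aggregated disagree in feature, length, or alignment."""


class PipelineError(ElectromeError, RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""
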