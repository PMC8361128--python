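"""Exception hierarchy for the pupilscreen pipeline."""


class PupilscreenError(Exception):
    """Base class for all pipeline errors."""


class SchemaError(PupilscreenError):
    """A file or config does not have the expected structure."""


class ValidationError(PupilscreenError):
    """Data violates an invariant (non-monotonic time, unknown label, ...)."""


class ParameterError(PupilscreenError):
    """An operation was called with an invalid parameter value."""


class TooSparseError(PupilscreenError):
    """A trial has too few observed samples for the requested operation."""


class WindowError(PupilscreenError):
    """A trial does not span a requested analysis window."""
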