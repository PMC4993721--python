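"""Exception hierarchy for thermoleaf."""


class ThermoleafError(Exception):
    """Base class for all thermoleaf errors."""


class ValidationError(ThermoleafError, ValueError):
    """Input violates a structural or physical constraint."""


class FrameParseError(ThermoleafError, ValueError):
    """A frame file could not be parsed as a rectangular numeric grid."""


class BoundsError(ThermoleafError, ValueError):
    """An ROI or pixel reference lies outside the frame."""


class ConfigurationError(ThermoleafError, ValueError):
    """A scene, ROI or run configuration is inconsistent."""


class DomainError(ThermoleafError, ValueError):
    """A quantity was requested outside its mathematical domain."""


class InsufficientDataError(ThermoleafError, ValueError):
    """Too few observations for the requested estimate."""


class PipelineError(ThermoleafError, RuntimeError):
    """A pipeline stage failed; the message names the stage and offending item."""
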