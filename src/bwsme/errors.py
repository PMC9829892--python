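"""Exception hierarchy for bwsme."""


class BwsmeError(Exception):
    """Base class for all package errors."""


class StructureError(BwsmeError):
    """Malformed or incomplete input structure (missing chain, backbone gaps...)."""


class AnnotationError(BwsmeError):
    """Secondary-structure annotation does not match the structure."""


class CalibrationError(BwsmeError):
    """The requested calibration target cannot be bracketed."""


class ConfigError(BwsmeError):
    """Invalid run configuration."""
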