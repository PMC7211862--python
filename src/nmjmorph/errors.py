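"""Exception hierarchy shared across the package."""


class NMJMorphError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(NMJMorphError):
    """A run configuration is invalid or incomplete."""


class CalibrationError(ConfigurationError):
    """No spatial calibration could be determined for an image."""


class EmptyMaskError(NMJMorphError):
    """An operation requiring foreground received an empty mask."""
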