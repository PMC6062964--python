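"""Exception hierarchy used across the pipeline."""


class HippomorphError(Exception):
    """Base class for all package-specific errors."""


class ContourFormatError(HippomorphError):
    """A contour file could not be parsed (message names the offending line)."""


class ValidationError(HippomorphError):
    """Parsed data violate a geometric or tabular invariant."""


class ConfigError(HippomorphError):
    """A configuration value is out of its admissible range."""
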