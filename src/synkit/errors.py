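"""Exception hierarchy shared across the package."""


class SynkitError(Exception):
    """Base class for all package-specific errors."""


class HexColorError(SynkitError, ValueError):
    """A string could not be parsed as a #RRGGBB hex color."""


class ColorRangeError(SynkitError, ValueError):
    """An sRGB coordinate fell outside the unit interval."""


class SpaceMismatchError(SynkitError, ValueError):
    """Two colors from different color spaces were combined."""


class ConfigError(SynkitError, ValueError):
    """Invalid configuration (missing column, bad parameter value)."""


class DataFormatError(SynkitError, ValueError):
    """Input trial data violate the expected layout."""


class GenerationError(SynkitError, RuntimeError):
    """A synthetic-data request could not be satisfied."""
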