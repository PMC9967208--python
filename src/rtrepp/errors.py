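"""Exception hierarchy shared across the package."""


class RtReppError(Exception):
    """Base class for all package-specific errors."""


class InvalidBoxError(RtReppError, ValueError):
    """A bounding box violates its invariants (non-positive extent, non-finite coords)."""


class SchemaError(RtReppError, ValueError):
    """An input file does not conform to the documented schema."""


class ConfigError(RtReppError, ValueError):
    """A configuration value is out of range or inconsistent."""


class DegenerateTrainingError(RtReppError, ValueError):
    """Link-scorer training data contains fewer than two classes."""
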