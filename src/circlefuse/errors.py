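"""Exception hierarchy shared across the package."""


class CircleFuseError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(CircleFuseError, ValueError):
    """A circle violates its geometric contract (e.g. non-positive radius)."""


class InvalidInputError(CircleFuseError, ValueError):
    """An operation received input missing a required field (e.g. a score)."""


class SchemaError(CircleFuseError, ValueError):
    """A tabular file does not match the expected column schema."""


class PackingError(CircleFuseError, RuntimeError):
    """Rejection sampling could not place the requested non-overlapping circles."""


class ConfigError(CircleFuseError, ValueError):
    """A configuration value is out of its documented range."""
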