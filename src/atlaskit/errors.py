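"""Exception hierarchy shared across atlaskit modules."""


class AtlasError(Exception):
    """Base class for all atlaskit errors."""


class ConfigurationError(AtlasError, ValueError):
    """An invalid generator or pipeline configuration; the message names the field."""


class DimensionError(AtlasError, ValueError):
    """Axes of two objects do not match, or an axis is too short for the operation."""


class DomainError(AtlasError, ValueError):
    """A numeric argument lies outside the mathematical domain of the operation."""


class InputError(AtlasError, ValueError):
    """Malformed input data; the message names the offending record."""
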