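"""Exception types."""


class RepgenError(Exception):
    """Base class for package errors."""


class ConfigError(RepgenError):
    """Invalid run or model configuration."""


class StructureError(ConfigError):
    """Invalid recombination-model structure declaration (e.g. cyclic graph)."""


class ModelValidationError(RepgenError):
    """A model violates its normalization/consistency contracts."""


class EventRangeError(RepgenError):
    """A scenario event value lies outside the model's event space."""


class InputError(RepgenError):
    """Malformed input file or record."""
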