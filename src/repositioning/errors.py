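"""Exception taxonomy shared across the package."""


class RepositioningError(Exception):
    """Base class for all package errors."""


class FormatError(RepositioningError):
    """A file does not conform to its declared format."""


class ValidationError(RepositioningError):
    """An in-memory object violates a documented invariant."""


class SignatureError(RepositioningError):
    """A signature operation produced an unusable (e.g. empty) signature."""


class ConfigError(RepositioningError):
    """A run configuration is missing, malformed, or contains unknown keys."""
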