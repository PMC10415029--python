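"""Exception hierarchy.

Argument errors (bad caller input such as an empty query or an unknown portion
label) raise the builtin :class:`ValueError`; everything domain-specific
derives from :class:`I2NError`.
"""


class I2NError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(I2NError):
    """Unknown dialect or malformed dialect/column-map configuration."""


class EmptyDatabaseError(I2NError):
    """A food-composition file yielded zero valid records."""


class RegistryConflictError(I2NError):
    """A database name is already registered."""


class NoDatabaseError(I2NError):
    """Search attempted on a registry with no databases."""


class ResolutionError(I2NError):
    """A (source_db, food_id) reference does not resolve in the registry."""


class ValidationError(I2NError):
    """Domain invariant violated (bad label, leftover exceeding initial, ...)."""


class DataFormatError(I2NError):
    """Unreadable, truncated, or schema-incompatible persisted file."""


class EmptyReportError(I2NError):
    """A report was requested over zero annotated items."""
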