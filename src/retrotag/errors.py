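"""Exception hierarchy.

All package-specific failures derive from :class:`RetroTagError` so callers
can distinguish chemistry/data errors from programming errors.
"""


class RetroTagError(Exception):
    """Base class for all retrotag errors."""


class ReactionParseError(RetroTagError):
    """A reaction line or SMILES fragment could not be parsed."""


class MultiplicityError(ReactionParseError):
    """The product side does not contain exactly one species."""


class MappingError(RetroTagError):
    """Atom-map numbers violate the reaction-mapping invariants."""


class TokenizationError(RetroTagError):
    """A SMILES string contains characters outside the token grammar."""


class TaggingError(RetroTagError):
    """A disconnection site cannot be placed on or read from a product."""


class DatasetError(RetroTagError):
    """Corpus construction, split assignment, or corpus I/O failed."""


class TemplateError(RetroTagError):
    """A reaction template could not be registered or applied."""
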