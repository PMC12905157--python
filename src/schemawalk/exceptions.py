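"""Exception hierarchy for schemawalk.

All errors raised by the library derive from :class:`SchemawalkError` so
callers can catch one base class at pipeline boundaries.
"""


class SchemawalkError(Exception):
    """Base class for all schemawalk errors."""


class FormatError(SchemawalkError):
    """A file does not conform to the expected tabular/YAML layout."""


class IntegrityError(SchemawalkError):
    """Data violates an internal consistency constraint (duplicates,
    references to records outside the allowed set, ...)."""


class SchemaError(SchemawalkError):
    """A schema definition is internally inconsistent (dangling slot or
    mixin reference, missing class list, ...)."""


class ParseError(FormatError):
    """A record could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class VocabularyError(SchemawalkError):
    """A token is outside the allowed controlled vocabulary (unknown
    mapping predicate, unknown requirement level, ...)."""


class ConfigError(SchemawalkError):
    """An invalid run or generator configuration."""
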