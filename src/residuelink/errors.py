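"""Exception hierarchy shared across the pipeline stages."""


class ResidueLinkError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(ResidueLinkError):
    """An input file could not be parsed (malformed XML/JSON)."""


class EmptyDocumentError(ResidueLinkError):
    """A JATS article contained no section/paragraph running text."""


class MetadataConflictError(ResidueLinkError):
    """Lookup records disagree on a metadata field (e.g. licence)."""

    def __init__(self, field: str, sources: list) -> None:
        self.field = field
        self.sources = list(sources)
        super().__init__(
            f"conflicting values for {field!r} across lookup records: {self.sources}"
        )


class ConfigurationError(ResidueLinkError):
    """A pipeline configuration value is invalid (e.g. unknown backend)."""


class SchemaError(ResidueLinkError):
    """An annotation document violates the shipped JSON schema."""

    def __init__(self, path: str, message: str) -> None:
        self.path = path
        super().__init__(f"{path}: {message}")


class InputError(ResidueLinkError):
    """Evaluation input violates a precondition (e.g. overlapping spans)."""


class FixtureSpecError(ResidueLinkError):
    """A synthetic-bundle specification is internally infeasible."""
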