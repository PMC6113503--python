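"""Exception hierarchy. Everything user-facing derives from GochronError."""


class GochronError(Exception):
    """Base class for all gochron domain errors."""


class OboParseError(GochronError):
    """Unparseable OBO stanza or line; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class OntologyStructureError(GochronError):
    """DAG invariant violated (cycle, dangling edge endpoint)."""


class TermLookupError(GochronError, LookupError):
    """Unknown or obsolete term requested from an ontology edition."""


class GafParseError(GochronError):
    """Malformed GAF line; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class AmbiguousMappingError(GochronError):
    """A secondary accession maps to more than one primary accession."""


class MatchingError(GochronError, LookupError):
    """No ontology edition at or before the requested annotation date."""


class InsufficientDataError(GochronError):
    """Too few observations for the requested statistic."""


class ConfigurationError(GochronError):
    """Invalid analysis configuration (empty background, bad corpus, ...)."""


class EmptyOverlapError(GochronError):
    """Hit list shares no genes with the annotated background."""
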