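"""Exception and warning types shared across the package."""


class SmartProtocolsError(Exception):
    """Base class for all errors raised by this package."""


class CycleError(SmartProtocolsError):
    """Precedence links among workflow units form a cycle."""


class DanglingPrecedenceError(SmartProtocolsError):
    """A preceded_by link references an id that does not exist among siblings."""


class EmptyStepsError(SmartProtocolsError):
    """A procedure container cannot be built from an empty step list."""


class InvalidProtocolError(SmartProtocolsError):
    """The protocol has structural validation errors and cannot be exported."""


class ProtocolSyntaxError(SmartProtocolsError):
    """The interchange document is not well-formed; carries line/column."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        loc = f" (line {line}, column {column})" if line is not None else ""
        super().__init__(f"{message}{loc}")


class SchemaError(SmartProtocolsError):
    """The interchange document violates the schema; carries the offending path."""

    def __init__(self, message: str, path: str = ""):
        self.path = path
        loc = f" at {path}" if path else ""
        super().__init__(f"{message}{loc}")


class ConfigError(SmartProtocolsError):
    """Invalid synthetic-protocol generator configuration."""


class DuplicateLabelError(SmartProtocolsError):
    """A (prefix, label) pair was registered twice in the term registry."""


class UnknownPrefixError(SmartProtocolsError):
    """A CURIE or term reference uses a prefix absent from the registry."""


class UnregisteredTermError(SmartProtocolsError):
    """An emission rule referenced a vocabulary term missing from the registry."""


class SlugCollisionError(SmartProtocolsError):
    """Two distinct local identifiers slug to the same IRI within one protocol."""


class MissingTypeError(SmartProtocolsError):
    """An RDF node lacks a recognized type and cannot be mapped back."""


class OrphanStepError(SmartProtocolsError):
    """A subprocedure node is not linked to any procedure."""


class MissingMockError(SmartProtocolsError):
    """A competency query requires a mock linked-data graph that was not provided."""


class AmbiguityWarning(UserWarning):
    """Precedence links define only a partial order; ties broken by input order."""


class UnknownTripleWarning(UserWarning):
    """A triple in the input graph matched no emission rule and was ignored."""
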