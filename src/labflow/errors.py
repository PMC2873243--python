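"""Exception hierarchy for labflow.

All labflow errors derive from :class:`LabflowError` so callers can catch
one base class at the CLI boundary.
"""


class LabflowError(Exception):
    """Base class for all labflow errors."""


class ParseError(LabflowError):
    """An input document could not be parsed (malformed RDF or XML)."""


class ScaffoldError(LabflowError):
    """The ontology lacks the required scaffold classes (Action, Equipment, Datatype)."""


class DuplicateNameError(LabflowError):
    """A name is already registered with a different payload."""


class UnknownTypeError(LabflowError):
    """A datatype reference does not resolve to an equipment class or scalar property."""


class UnknownClassError(LabflowError):
    """A class name does not resolve in the ontology."""


class UnknownIndividualError(LabflowError):
    """An equipment binding names an individual that does not exist."""


class UnknownApplicationError(LabflowError):
    """An activity invokes an application absent from the translation unit."""


class UnknownVariableError(LabflowError):
    """An activity binds a variable that has not been declared."""


class UnknownActivityError(LabflowError):
    """A transition endpoint names an activity that does not exist."""


class MissingDeclarationError(LabflowError):
    """A template parameter's datatype has no XPDL declaration."""


class ConformanceError(LabflowError):
    """The ontology violates the parameter-layer schema and cannot be translated."""

    def __init__(self, message, findings=()):
        super().__init__(message)
        self.findings = list(findings)


class CycleError(LabflowError):
    """The unconditional transition graph contains a cycle."""


class ValidationError(LabflowError):
    """Serialization refused: the protocol has typecheck errors."""

    def __init__(self, message, diagnostics=()):
        super().__init__(message)
        self.diagnostics = list(diagnostics)


class SchemaError(LabflowError):
    """An XPDL document does not validate against the vendored schema."""


class LinkageError(LabflowError):
    """A cross-file reference (ExternalReference xref or bound individual) is dangling."""


class PathError(LabflowError):
    """An output location does not exist or is not writable."""
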