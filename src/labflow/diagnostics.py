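"""Machine-readable findings produced by conformance checking and typechecking.

A :class:`Diagnostic` pairs an enumerated code with a location inside the
artifact being checked (ontology template, protocol activity, parameter).
Severity is a fixed function of the code: the table below is the single
source of truth, so a given defect class can never be downgraded at one
call site and not another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

# -- diagnostic codes ---------------------------------------------------------

# Ontology / parameter-layer conformance
PARAM_TYPE_NOT_DATATYPE = "PARAM_TYPE_NOT_DATATYPE"
DUPLICATE_POSITION = "DUPLICATE_POSITION"
POSITION_GAP = "POSITION_GAP"
UNRESOLVED_REFERENCE = "UNRESOLVED_REFERENCE"
NAME_COLLISION = "NAME_COLLISION"
PARENT_CYCLE = "PARENT_CYCLE"
UNCLASSIFIED_GOAL = "UNCLASSIFIED_GOAL"

# Protocol typechecking
TYPE_MISMATCH = "TYPE_MISMATCH"
UNBOUND_INPUT = "UNBOUND_INPUT"
UNKNOWN_APPLICATION = "UNKNOWN_APPLICATION"
UNKNOWN_VARIABLE = "UNKNOWN_VARIABLE"
UNKNOWN_INDIVIDUAL = "UNKNOWN_INDIVIDUAL"
UNREACHABLE_ACTIVITY = "UNREACHABLE_ACTIVITY"
ARITY_MISMATCH = "ARITY_MISMATCH"
OUT_PARAM_LITERAL = "OUT_PARAM_LITERAL"
MISSING_UNIT = "MISSING_UNIT"
UNUSED_VARIABLE = "UNUSED_VARIABLE"

# Cross-file linkage (reported when reading a package)
DANGLING_XREF = "DANGLING_XREF"
MISSING_INDIVIDUAL = "MISSING_INDIVIDUAL"

#: code -> severity; every code the package can emit appears here exactly once.
SEVERITY_TABLE: dict[str, str] = {
    PARAM_TYPE_NOT_DATATYPE: "error",
    DUPLICATE_POSITION: "error",
    POSITION_GAP: "error",
    UNRESOLVED_REFERENCE: "error",
    NAME_COLLISION: "error",
    PARENT_CYCLE: "error",
    UNCLASSIFIED_GOAL: "warning",
    TYPE_MISMATCH: "error",
    UNBOUND_INPUT: "error",
    UNKNOWN_APPLICATION: "error",
    UNKNOWN_VARIABLE: "error",
    UNKNOWN_INDIVIDUAL: "error",
    UNREACHABLE_ACTIVITY: "error",
    ARITY_MISMATCH: "error",
    OUT_PARAM_LITERAL: "error",
    MISSING_UNIT: "error",
    UNUSED_VARIABLE: "warning",
    DANGLING_XREF: "error",
    MISSING_INDIVIDUAL: "error",
}


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding.

    ``location`` is a slash-separated path into the checked artifact, e.g.
    ``"activity/add_lysis_buffer/param/volume"`` or ``"template/tmpl2/param/p1"``.
    """

    code: str
    location: str
    message: str

    def __post_init__(self) -> None:
        if self.code not in SEVERITY_TABLE:
            raise ValueError(f"unknown diagnostic code: {self.code}")

    @property
    def severity(self) -> str:
        return SEVERITY_TABLE[self.code]

    @property
    def is_error(self) -> bool:
        return self.severity == "error"

    def to_json(self) -> str:
        """Render as a single JSON line (code, severity, location, message)."""
        return json.dumps(
            {
                "code": self.code,
                "severity": self.severity,
                "location": self.location,
                "message": self.message,
            },
            sort_keys=True,
        )


def errors_of(diagnostics) -> list[Diagnostic]:
    """The error-severity subset of ``diagnostics``, order preserved."""
    return [d for d in diagnostics if d.is_error]
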