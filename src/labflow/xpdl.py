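"""Model-to-model transformation from the ontology to XPDL declarations.

Action templates (ontology individuals of an action class, each with an
ordered IN / OUT / IN_OUT parameter signature) map one-to-one onto XPDL
``Application`` declarations; every member of the ``Datatype`` union
(equipment classes and scalar properties) maps onto an XPDL
``TypeDeclaration`` that points back at the ontology concept through an
``ExternalReference`` instead of inlining a copy.  The transformation is
deterministic: identifiers are sanitized local names with collisions resolved
by numeric suffixes, and output ordering is lexicographic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from .diagnostics import errors_of
from .errors import ConformanceError, MissingDeclarationError, UnknownTypeError
from .ontology import (
    ActionTemplate,
    DatatypeRef,
    DomainOntology,
    validate_ungap_conformance,
)

Mode = Literal["IN", "OUT", "INOUT"]

#: template parameter direction -> XPDL formal-parameter mode
DIRECTION_TO_MODE: Mapping[str, Mode] = {"IN": "IN", "OUT": "OUT", "IN_OUT": "INOUT"}
MODE_TO_DIRECTION = {v: k for k, v in DIRECTION_TO_MODE.items()}

_ID_RE = re.compile(r"[^A-Za-z0-9_]+")


def sanitize_id(name: str) -> str:
    """An XPDL-safe identifier: alphanumerics and underscores only."""
    out = _ID_RE.sub("_", name).strip("_") or "id"
    if out[0].isdigit():
        out = "_" + out
    return out


def assign_ids(names: Iterable[str]) -> dict[str, str]:
    """Map each name to a unique sanitized id.

    Collisions get numeric suffixes assigned in lexicographic order of the
    original names, so the mapping is stable across runs.
    """
    ids: dict[str, str] = {}
    taken: set[str] = set()
    for name in sorted(set(names)):
        base = sanitize_id(name)
        candidate, k = base, 2
        while candidate in taken:
            candidate = f"{base}_{k}"
            k += 1
        ids[name] = candidate
        taken.add(candidate)
    return ids


@dataclass(frozen=True)
class DataTypeDecl:
    """An XPDL TypeDeclaration referencing an ontology concept externally."""

    id: str
    name: str
    external_location: str
    external_xref: str


@dataclass(frozen=True)
class FormalParameter:
    name: str
    mode: Mode
    datatype_decl: str  # id of a DataTypeDecl
    position: int


@dataclass(frozen=True)
class ApplicationDef:
    """The XPDL Application produced from one action template."""

    id: str
    name: str
    formal_params: tuple[FormalParameter, ...] = ()
    description: str = ""
    source_template: str = ""


@dataclass
class TranslationUnit:
    """All Applications and TypeDeclarations derived from one ontology."""

    source_ontology_iri: str = ""
    applications: dict[str, ApplicationDef] = field(default_factory=dict)
    datatype_decls: dict[str, DataTypeDecl] = field(default_factory=dict)

    def application_for_template(self, template_name: str) -> ApplicationDef:
        for app in self.applications.values():
            if app.source_template == template_name:
                return app
        raise KeyError(template_name)

    def decl_for_concept(self, concept_name: str) -> DataTypeDecl:
        for d in self.datatype_decls.values():
            if d.external_xref == concept_name:
                return d
        raise KeyError(concept_name)


def datatype_to_xpdl(ref: DatatypeRef, location: str, ont: DomainOntology) -> DataTypeDecl:
    """Translate one datatype reference into a TypeDeclaration.

    The declaration carries an external reference (``location`` is the
    relative path/IRI of the OWL file, the xref the concept's local name);
    the ontology concept itself is never copied.  Translating the same
    reference twice yields an identical declaration.
    """
    ont.resolve(ref)  # raises UnknownTypeError for unresolvable refs
    return DataTypeDecl(
        id=sanitize_id(ref.target),
        name=ref.target,
        external_location=location,
        external_xref=ref.target,
    )


def template_to_application(template: ActionTemplate,
                            decls: Mapping[str, DataTypeDecl],
                            app_id: str | None = None) -> ApplicationDef:
    """Translate one action template into an Application declaration.

    Formal parameter names, order and the direction-to-mode mapping
    (IN→IN, OUT→OUT, IN_OUT→INOUT) are preserved.  ``decls`` must already
    declare every datatype the template's parameters use, keyed or valued by
    concept name; otherwise :class:`MissingDeclarationError` is raised.
    """
    by_concept = {d.external_xref: d for d in decls.values()}
    formals = []
    for p in sorted(template.params, key=lambda p: p.position):
        decl = by_concept.get(p.datatype.target)
        if decl is None:
            raise MissingDeclarationError(
                f"template {template.name!r}: datatype {p.datatype.target!r} has no declaration")
        formals.append(FormalParameter(
            name=p.name,
            mode=DIRECTION_TO_MODE[p.direction],
            datatype_decl=decl.id,
            position=p.position,
        ))
    return ApplicationDef(
        id=app_id or sanitize_id(template.name),
        name=template.name,
        formal_params=tuple(formals),
        description=template.description,
        source_template=template.name,
    )


def translate_ontology(ont: DomainOntology, dso_location: str = "dso.owl") -> TranslationUnit:
    """Translate a conformant ontology into a full translation unit.

    Every equipment class and scalar property is declared (even if no
    template references it — completeness over minimality), and templates
    map bijectively onto Applications with deterministic ids.  Non-conformant
    input is refused with :class:`ConformanceError`.
    """
    report = validate_ungap_conformance(ont)
    if not report.conformant:
        raise ConformanceError(
            "ontology is not conformant; refusing to translate",
            findings=errors_of(report.findings))

    concept_names = sorted(ont.datatype_names())
    concept_ids = assign_ids(concept_names)
    tu = TranslationUnit(source_ontology_iri=ont.iri)
    for name in concept_names:
        kind = "equipment" if name in ont.equipment_classes else "scalar"
        decl = DataTypeDecl(
            id=concept_ids[name],
            name=name,
            external_location=dso_location,
            external_xref=name,
        )
        tu.datatype_decls[decl.id] = decl

    template_ids = assign_ids(ont.templates)
    for tname in sorted(ont.templates):
        app = template_to_application(ont.templates[tname], tu.datatype_decls,
                                      app_id=template_ids[tname])
        tu.applications[app.id] = app
    return tu
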