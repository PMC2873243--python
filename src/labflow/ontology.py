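"""In-memory model of the laboratory ontology stack and its OWL serialization.

The stack has three layers:

* a minimal *core* of experimental actions and equipment: an ``Action`` class
  with three goal branches (``Separation``, ``Transformation``,
  ``Combination`` — actions are classified by whether they separate,
  transform, or combine material), an ``Equipment`` class with ``ActiveEntity``
  (can perform actions) and ``PassiveEntity`` (is acted upon) branches;
* a *parameter layer* that restructures actions so that each action template
  declares ordered IN / OUT / IN_OUT parameter lists, and that defines the
  ``Datatype`` class — the union of ``Equipment`` and unit-bearing scalar
  properties — as the type system those parameters draw from;
* a *domain-specific ontology* (DSO): a laboratory's own action classes,
  equipment classes, scalar properties, action templates and equipment
  individuals, attached under the core.

A :class:`DomainOntology` holds the whole stack in one object.  OWL files are
read and written with :mod:`rdflib` as RDF/XML (primary) or Turtle.

Ordered parameters in OWL
-------------------------
OWL property values are unordered, so each parameter specification is an
individual carrying an explicit integer ``parameterPosition`` annotation;
positions within a template must be consecutive from 0.

Scalar units
------------
Scalar properties follow the suffix naming convention ``<name>_<unit>``
(e.g. ``volumeQuantity_ul``).  The unit is stored as a separate field: on
load an explicit ``unit`` annotation wins, else the trailing ``_<unit>``
token is parsed if recognized, else the property is treated as unitless text.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Union

from rdflib import Graph, Literal as RDFLiteral, Namespace, RDF, RDFS, OWL, URIRef, XSD

from .diagnostics import (
    DUPLICATE_POSITION,
    NAME_COLLISION,
    PARAM_TYPE_NOT_DATATYPE,
    PARENT_CYCLE,
    POSITION_GAP,
    UNCLASSIFIED_GOAL,
    UNRESOLVED_REFERENCE,
    Diagnostic,
    errors_of,
)
from .errors import (
    DuplicateNameError,
    ParseError,
    ScaffoldError,
    UnknownClassError,
    UnknownTypeError,
)

Goal = Literal["separation", "transformation", "combination", "unclassified"]
Agency = Literal["active", "passive", "unspecified"]
Direction = Literal["IN", "OUT", "IN_OUT"]

#: Default namespaces; overridable at load/save time.
CORE_BASE_IRI = "http://labflow.example.org/ontology/core"
DEFAULT_DSO_IRI = "http://labflow.example.org/ontology/dso"

#: Core class names reserved by the scaffold.
CORE_ACTION_CLASSES = {
    "Action": (None, "unclassified"),
    "Separation": ("Action", "separation"),
    "Transformation": ("Action", "transformation"),
    "Combination": ("Action", "combination"),
}
CORE_EQUIPMENT_CLASSES = {
    "Equipment": (None, "unspecified"),
    "ActiveEntity": ("Equipment", "active"),
    "PassiveEntity": ("Equipment", "passive"),
}

#: Unit suffixes recognized when parsing ``<name>_<unit>`` scalar names.
KNOWN_UNIT_SUFFIXES = (
    "ul", "ml", "l", "ng", "ug", "mg", "g",
    "s", "sec", "min", "h",
    "celsius", "rpm", "pct", "x", "mm", "cm", "nm",
)

DIRECTIONS: tuple[Direction, ...] = ("IN", "OUT", "IN_OUT")
GOALS: tuple[Goal, ...] = ("separation", "transformation", "combination", "unclassified")
AGENCIES: tuple[Agency, ...] = ("active", "passive", "unspecified")


@dataclass(frozen=True)
class ActionClass:
    """An action concept; ``goal`` is the *declared* goal (``unclassified``
    means inherited — see :func:`goal_category`)."""

    name: str
    parent: Optional[str] = None
    goal: Goal = "unclassified"


@dataclass(frozen=True)
class EquipmentClass:
    """An equipment concept; ``agency`` declared analogously to goals."""

    name: str
    parent: Optional[str] = None
    agency: Agency = "unspecified"


@dataclass(frozen=True)
class ScalarProperty:
    """A unit-bearing scalar parameter type (an ``owl:DatatypeProperty``)."""

    name: str
    unit: str = ""
    value_kind: Literal["decimal", "integer", "text"] = "decimal"

    def __post_init__(self) -> None:
        if self.value_kind in ("decimal", "integer") and not self.unit:
            raise ValueError(f"scalar property {self.name!r}: {self.value_kind} kind requires a unit")


@dataclass(frozen=True)
class DatatypeRef:
    """A reference into the ``Datatype`` type system: either an equipment
    class or a scalar property, by name."""

    kind: Literal["equipment", "scalar"]
    target: str

    @classmethod
    def equipment(cls, target: str) -> "DatatypeRef":
        return cls("equipment", target)

    @classmethod
    def scalar(cls, target: str) -> "DatatypeRef":
        return cls("scalar", target)


@dataclass(frozen=True)
class ParameterSpec:
    name: str
    direction: Direction
    datatype: DatatypeRef
    position: int


@dataclass(frozen=True)
class ActionTemplate:
    """An individual of an action class with a fixed, ordered parameter
    signature — the reusable building block a protocol step invokes
    (e.g. ``add_reagent_to_container``)."""

    name: str
    action_class: str
    params: tuple[ParameterSpec, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        names = [p.name for p in self.params]
        if len(names) != len(set(names)):
            raise ValueError(f"template {self.name!r}: duplicate parameter names")


@dataclass(frozen=True)
class EquipmentIndividual:
    name: str
    equipment_class: str


@dataclass(frozen=True)
class ConformanceReport:
    conformant: bool
    findings: tuple[Diagnostic, ...]


@dataclass
class DomainOntology:
    """The full ontology stack: core scaffold plus DSO extensions."""

    iri: str = DEFAULT_DSO_IRI
    core_iri: str = CORE_BASE_IRI
    action_classes: dict[str, ActionClass] = field(default_factory=dict)
    equipment_classes: dict[str, EquipmentClass] = field(default_factory=dict)
    scalar_properties: dict[str, ScalarProperty] = field(default_factory=dict)
    templates: dict[str, ActionTemplate] = field(default_factory=dict)
    individuals: dict[str, EquipmentIndividual] = field(default_factory=dict)

    # -- construction --------------------------------------------------------

    @classmethod
    def scaffold(cls, iri: str = DEFAULT_DSO_IRI, core_iri: str = CORE_BASE_IRI) -> "DomainOntology":
        """A fresh ontology containing only the core classes."""
        ont = cls(iri=iri, core_iri=core_iri)
        for name, (parent, goal) in CORE_ACTION_CLASSES.items():
            ont.action_classes[name] = ActionClass(name, parent, goal)
        for name, (parent, agency) in CORE_EQUIPMENT_CLASSES.items():
            ont.equipment_classes[name] = EquipmentClass(name, parent, agency)
        return ont

    def copy(self) -> "DomainOntology":
        return copy.deepcopy(self)

    # -- lookups -------------------------------------------------------------

    def resolve(self, ref: DatatypeRef) -> Union[EquipmentClass, ScalarProperty]:
        """Resolve a datatype reference or raise :class:`UnknownTypeError`."""
        if ref.kind == "equipment":
            try:
                return self.equipment_classes[ref.target]
            except KeyError:
                raise UnknownTypeError(f"unknown equipment class: {ref.target!r}") from None
        try:
            return self.scalar_properties[ref.target]
        except KeyError:
            raise UnknownTypeError(f"unknown scalar property: {ref.target!r}") from None

    def datatype_names(self) -> set[str]:
        """All names in the ``Datatype`` union (equipment ∪ scalar)."""
        return set(self.equipment_classes) | set(self.scalar_properties)

    def _ancestors(self, name: str, table: dict) -> Iterable[str]:
        """Yield name, parent, grandparent, ... (cycle-safe)."""
        seen = set()
        cur: Optional[str] = name
        while cur is not None and cur not in seen:
            seen.add(cur)
            yield cur
            node = table.get(cur)
            cur = node.parent if node is not None else None

    def action_ancestors(self, name: str) -> list[str]:
        return list(self._ancestors(name, self.action_classes))

    def equipment_ancestors(self, name: str) -> list[str]:
        return list(self._ancestors(name, self.equipment_classes))

    # -- mutation ------------------------------------------------------------

    def add_action_class(self, name: str, parent: Optional[str] = None,
                         goal: Goal = "unclassified") -> "DomainOntology":
        ac = ActionClass(name, parent, goal)
        existing = self.action_classes.get(name)
        if existing is not None:
            if existing != ac:
                raise DuplicateNameError(f"action class {name!r} already defined differently")
            return self
        if parent is not None and parent not in self.action_classes:
            raise UnknownClassError(f"unknown parent action class: {parent!r}")
        self.action_classes[name] = ac
        return self

    def add_equipment_class(self, name: str, parent: Optional[str] = "Equipment",
                            agency: Agency = "unspecified") -> "DomainOntology":
        ec = EquipmentClass(name, parent, agency)
        existing = self.equipment_classes.get(name)
        if existing is not None:
            if existing != ec:
                raise DuplicateNameError(f"equipment class {name!r} already defined differently")
            return self
        if parent is not None and parent not in self.equipment_classes:
            raise UnknownClassError(f"unknown parent equipment class: {parent!r}")
        self.equipment_classes[name] = ec
        return self

    def add_scalar_property(self, name: str, unit: str = "",
                            value_kind: str = "decimal") -> "DomainOntology":
        if not unit:
            parsed = parse_unit_suffix(name)
            if parsed:
                unit = parsed
            elif value_kind != "text":
                value_kind = "text"
        sp = ScalarProperty(name, unit, value_kind)  # type: ignore[arg-type]
        existing = self.scalar_properties.get(name)
        if existing is not None:
            if existing != sp:
                raise DuplicateNameError(f"scalar property {name!r} already defined differently")
            return self
        self.scalar_properties[name] = sp
        return self

    def add_action_template(self, name: str, action_class: str,
                            params: Iterable[ParameterSpec] = (),
                            description: str = "") -> "DomainOntology":
        """Register a reusable action template.

        Re-adding an identical template is a no-op; a different payload under
        an existing name raises :class:`DuplicateNameError`.
        """
        t = ActionTemplate(name, action_class, tuple(params), description)
        existing = self.templates.get(name)
        if existing is not None:
            if existing != t:
                raise DuplicateNameError(f"template {name!r} already defined differently")
            return self
        if action_class not in self.action_classes:
            raise UnknownClassError(f"unknown action class: {action_class!r}")
        for p in t.params:
            self.resolve(p.datatype)  # raises UnknownTypeError
        self.templates[name] = t
        return self

    def add_individual(self, name: str, equipment_class: str) -> "DomainOntology":
        ind = EquipmentIndividual(name, equipment_class)
        existing = self.individuals.get(name)
        if existing is not None:
            if existing != ind:
                raise DuplicateNameError(f"individual {name!r} already defined differently")
            return self
        if equipment_class not in self.equipment_classes:
            raise UnknownClassError(f"unknown equipment class: {equipment_class!r}")
        self.individuals[name] = ind
        return self


def parse_unit_suffix(name: str) -> str:
    """The unit encoded in a trailing ``_<unit>`` token, or ``""``."""
    if "_" not in name:
        return ""
    suffix = name.rsplit("_", 1)[1].lower()
    return suffix if suffix in KNOWN_UNIT_SUFFIXES else ""


# -- goal / agency resolution -------------------------------------------------

def goal_category(ont: DomainOntology, action_class: Union[str, ActionClass]) -> Goal:
    """Effective goal of an action class: the nearest ancestor's declared
    goal, ``unclassified`` if no ancestor declares one."""
    name = action_class.name if isinstance(action_class, ActionClass) else action_class
    if name not in ont.action_classes:
        raise UnknownClassError(f"unknown action class: {name!r}")
    for anc in ont.action_ancestors(name):
        declared = ont.action_classes[anc].goal
        if declared != "unclassified":
            return declared
    return "unclassified"


def agency_category(ont: DomainOntology, equipment_class: Union[str, EquipmentClass]) -> Agency:
    """Effective agency, inherited like :func:`goal_category`."""
    name = equipment_class.name if isinstance(equipment_class, EquipmentClass) else equipment_class
    if name not in ont.equipment_classes:
        raise UnknownClassError(f"unknown equipment class: {name!r}")
    for anc in ont.equipment_ancestors(name):
        declared = ont.equipment_classes[anc].agency
        if declared != "unspecified":
            return declared
    return "unspecified"


# -- conformance --------------------------------------------------------------

def _has_cycle(name: str, table: dict) -> bool:
    seen = set()
    cur = name
    while cur is not None:
        if cur in seen:
            return True
        seen.add(cur)
        node = table.get(cur)
        cur = node.parent if node is not None else None
    return False


def validate_ungap_conformance(ont: DomainOntology) -> ConformanceReport:
    """Check the parameter-layer schema; violations are reported, not raised.

    Errors: parameter typed outside the ``Datatype`` union, duplicate or
    non-consecutive parameter positions, unresolvable class references,
    equipment/scalar name collisions, parent cycles.  A DSO action class whose
    effective goal is unclassified is a warning only.
    """
    findings: list[Diagnostic] = []

    collisions = set(ont.equipment_classes) & set(ont.scalar_properties)
    for name in sorted(collisions):
        findings.append(Diagnostic(
            NAME_COLLISION, f"datatype/{name}",
            f"{name!r} is both an equipment class and a scalar property"))

    for name in sorted(ont.action_classes):
        if _has_cycle(name, ont.action_classes):
            findings.append(Diagnostic(PARENT_CYCLE, f"action_class/{name}",
                                       f"action class {name!r} is on a parent cycle"))
        else:
            parent = ont.action_classes[name].parent
            if parent is not None and parent not in ont.action_classes:
                findings.append(Diagnostic(UNRESOLVED_REFERENCE, f"action_class/{name}",
                                           f"parent {parent!r} not defined"))
    for name in sorted(ont.equipment_classes):
        if _has_cycle(name, ont.equipment_classes):
            findings.append(Diagnostic(PARENT_CYCLE, f"equipment_class/{name}",
                                       f"equipment class {name!r} is on a parent cycle"))
        else:
            parent = ont.equipment_classes[name].parent
            if parent is not None and parent not in ont.equipment_classes:
                findings.append(Diagnostic(UNRESOLVED_REFERENCE, f"equipment_class/{name}",
                                           f"parent {parent!r} not defined"))

    for tname in sorted(ont.templates):
        t = ont.templates[tname]
        if t.action_class not in ont.action_classes:
            findings.append(Diagnostic(UNRESOLVED_REFERENCE, f"template/{tname}",
                                       f"action class {t.action_class!r} not defined"))
        elif goal_category(ont, t.action_class) == "unclassified":
            findings.append(Diagnostic(UNCLASSIFIED_GOAL, f"template/{tname}",
                                       f"action class {t.action_class!r} has no goal ancestor"))
        positions = [p.position for p in t.params]
        if len(positions) != len(set(positions)):
            findings.append(Diagnostic(DUPLICATE_POSITION, f"template/{tname}",
                                       f"duplicate parameter positions {positions}"))
        elif sorted(positions) != list(range(len(positions))):
            findings.append(Diagnostic(POSITION_GAP, f"template/{tname}",
                                       f"positions {sorted(positions)} not consecutive from 0"))
        for p in t.params:
            loc = f"template/{tname}/param/{p.name}"
            if p.datatype.kind == "equipment":
                if p.datatype.target not in ont.equipment_classes:
                    if p.datatype.target in ont.action_classes:
                        findings.append(Diagnostic(
                            PARAM_TYPE_NOT_DATATYPE, loc,
                            f"{p.datatype.target!r} is an action class, outside Datatype"))
                    else:
                        findings.append(Diagnostic(
                            UNRESOLVED_REFERENCE, loc,
                            f"equipment class {p.datatype.target!r} not defined"))
            else:
                if p.datatype.target not in ont.scalar_properties:
                    if p.datatype.target in ont.action_classes:
                        findings.append(Diagnostic(
                            PARAM_TYPE_NOT_DATATYPE, loc,
                            f"{p.datatype.target!r} is an action class, outside Datatype"))
                    else:
                        findings.append(Diagnostic(
                            UNRESOLVED_REFERENCE, loc,
                            f"scalar property {p.datatype.target!r} not defined"))

    for iname in sorted(ont.individuals):
        ind = ont.individuals[iname]
        if ind.equipment_class not in ont.equipment_classes:
            findings.append(Diagnostic(UNRESOLVED_REFERENCE, f"individual/{iname}",
                                       f"equipment class {ind.equipment_class!r} not defined"))

    return ConformanceReport(conformant=not errors_of(findings), findings=tuple(findings))


# -- OWL serialization --------------------------------------------------------

_VK_TO_RANGE = {"decimal": XSD.decimal, "integer": XSD.integer, "text": XSD.string}
_RANGE_TO_VK = {str(v): k for k, v in _VK_TO_RANGE.items()}
_DIR_PROPS = {"IN": "paramIN", "OUT": "paramOUT", "IN_OUT": "paramIN_OUT"}
_PROP_DIRS = {v: k for k, v in _DIR_PROPS.items()}


def _core_ns(ont_or_iri) -> Namespace:
    iri = ont_or_iri.core_iri if isinstance(ont_or_iri, DomainOntology) else ont_or_iri
    return Namespace(iri + "#")


def _dso_ns(ont_or_iri) -> Namespace:
    iri = ont_or_iri.iri if isinstance(ont_or_iri, DomainOntology) else ont_or_iri
    return Namespace(iri + "#")


def save_domain_ontology(ont: DomainOntology, destination, format: str = "rdfxml") -> None:
    """Write the ontology stack to one OWL file (RDF/XML or Turtle).

    The output is deterministic: triples are inserted in sorted order so that
    repeated saves of equal ontologies are byte-identical.
    """
    g = ontology_to_graph(ont)
    fmt = {"rdfxml": "pretty-xml", "turtle": "turtle"}.get(format, format)
    data = g.serialize(format=fmt, encoding="utf-8")
    if hasattr(destination, "write"):
        destination.write(data)
    else:
        with open(destination, "wb") as fh:
            fh.write(data)


def ontology_to_graph(ont: DomainOntology) -> Graph:
    CORE = _core_ns(ont)
    DSO = _dso_ns(ont)

    def node(name: str) -> URIRef:
        if name in CORE_ACTION_CLASSES or name in CORE_EQUIPMENT_CLASSES:
            return CORE[name]
        return DSO[name]

    triples: list[tuple] = []
    triples.append((URIRef(ont.iri), RDF.type, OWL.Ontology))
    triples.append((URIRef(ont.iri), OWL.imports, URIRef(ont.core_iri)))

    # scaffold marker classes and annotation properties
    triples.append((CORE["Datatype"], RDF.type, OWL.Class))
    triples.append((CORE["ParameterSpec"], RDF.type, OWL.Class))
    for prop in ("goal", "agency", "unit", "parameterName", "parameterPosition",
                 "parameterDatatype", "paramIN", "paramOUT", "paramIN_OUT"):
        triples.append((CORE[prop], RDF.type, OWL.AnnotationProperty))
    triples.append((CORE["Equipment"], RDFS.subClassOf, CORE["Datatype"]))

    for name in sorted(ont.action_classes):
        ac = ont.action_classes[name]
        n = node(name)
        triples.append((n, RDF.type, OWL.Class))
        if ac.parent is not None:
            triples.append((n, RDFS.subClassOf, node(ac.parent)))
        elif name != "Action":
            triples.append((n, RDFS.subClassOf, CORE["Action"]))
        if ac.goal != "unclassified":
            triples.append((n, CORE["goal"], RDFLiteral(ac.goal)))

    for name in sorted(ont.equipment_classes):
        ec = ont.equipment_classes[name]
        n = node(name)
        triples.append((n, RDF.type, OWL.Class))
        if ec.parent is not None:
            triples.append((n, RDFS.subClassOf, node(ec.parent)))
        elif name != "Equipment":
            triples.append((n, RDFS.subClassOf, CORE["Equipment"]))
        if ec.agency != "unspecified":
            triples.append((n, CORE["agency"], RDFLiteral(ec.agency)))

    for name in sorted(ont.scalar_properties):
        sp = ont.scalar_properties[name]
        n = DSO[name]
        triples.append((n, RDF.type, OWL.DatatypeProperty))
        triples.append((n, RDFS.range, _VK_TO_RANGE[sp.value_kind]))
        if sp.unit:
            triples.append((n, CORE["unit"], RDFLiteral(sp.unit)))

    for tname in sorted(ont.templates):
        t = ont.templates[tname]
        tn = DSO[tname]
        triples.append((tn, RDF.type, OWL.NamedIndividual))
        triples.append((tn, RDF.type, node(t.action_class)))
        if t.description:
            triples.append((tn, RDFS.comment, RDFLiteral(t.description)))
        for p in t.params:
            pn = DSO[f"{tname}__param__{p.name}"]
            triples.append((tn, CORE[_DIR_PROPS[p.direction]], pn))
            triples.append((pn, RDF.type, CORE["ParameterSpec"]))
            triples.append((pn, CORE["parameterName"], RDFLiteral(p.name)))
            triples.append((pn, CORE["parameterPosition"],
                            RDFLiteral(p.position, datatype=XSD.integer)))
            target_node = (node(p.datatype.target)
                           if p.datatype.kind == "equipment" and (
                               p.datatype.target in ont.equipment_classes
                               or p.datatype.target in ont.action_classes)
                           else DSO[p.datatype.target])
            triples.append((pn, CORE["parameterDatatype"], target_node))

    for iname in sorted(ont.individuals):
        ind = ont.individuals[iname]
        n = DSO[iname]
        triples.append((n, RDF.type, OWL.NamedIndividual))
        triples.append((n, RDF.type, node(ind.equipment_class)))

    g = Graph()
    g.bind("owl", OWL)
    g.bind("core", CORE)
    g.bind("dso", DSO)
    for t in sorted(triples):
        g.add(t)
    return g


def _local(uri: URIRef) -> str:
    s = str(uri)
    if "#" in s:
        return s.rsplit("#", 1)[1]
    return s.rstrip("/").rsplit("/", 1)[-1]


def load_domain_ontology(source, format: Optional[str] = None) -> DomainOntology:
    """Load an ontology stack from an OWL document (RDF/XML or Turtle).

    ``source`` is a path or file-like object.  Raises :class:`ParseError` on
    malformed RDF and :class:`ScaffoldError` when the scaffold classes
    (``Action``, ``Equipment``, ``Datatype``) are absent.
    """
    g = Graph()
    errors = []
    formats = [format] if format else ["xml", "turtle"]
    parsed = False
    data = None
    if hasattr(source, "read"):
        data = source.read()
    for fmt in formats:
        try:
            if data is not None:
                g = Graph()
                g.parse(data=data, format=fmt)
            else:
                g = Graph()
                g.parse(source, format=fmt)
            parsed = True
            break
        except Exception as exc:  # rdflib raises assorted parser errors
            errors.append(f"{fmt}: {exc}")
    if not parsed:
        raise ParseError("could not parse ontology document: " + "; ".join(errors))

    # locate scaffold classes by local name
    classes = set(g.subjects(RDF.type, OWL.Class))
    by_local: dict[str, URIRef] = {}
    for c in classes:
        if isinstance(c, URIRef):
            by_local.setdefault(_local(c), c)
    missing = [n for n in ("Action", "Equipment", "Datatype") if n not in by_local]
    if missing:
        raise ScaffoldError(f"scaffold classes absent: {', '.join(missing)}")

    action_root = by_local["Action"]
    core_iri = str(action_root).rsplit("#", 1)[0]
    CORE = Namespace(core_iri + "#")

    ont_subjects = [s for s in g.subjects(RDF.type, OWL.Ontology) if isinstance(s, URIRef)]
    dso_iri = str(sorted(ont_subjects)[0]) if ont_subjects else DEFAULT_DSO_IRI
    ont = DomainOntology(iri=dso_iri, core_iri=core_iri)

    parents: dict[URIRef, Optional[URIRef]] = {}
    for c in classes:
        if not isinstance(c, URIRef):
            continue
        sup = [o for o in g.objects(c, RDFS.subClassOf) if isinstance(o, URIRef)]
        parents[c] = sorted(sup)[0] if sup else None

    def root_of(c: URIRef) -> Optional[URIRef]:
        seen = set()
        cur: Optional[URIRef] = c
        while cur is not None and cur not in seen:
            seen.add(cur)
            if cur == action_root:
                return action_root
            if cur == by_local["Equipment"]:
                return by_local["Equipment"]
            cur = parents.get(cur)
        return None

    marker_locals = {"Datatype", "ParameterSpec"}
    for c in sorted(classes):
        if not isinstance(c, URIRef) or _local(c) in marker_locals:
            continue
        root = root_of(c)
        name = _local(c)
        parent_uri = parents.get(c)
        parent = _local(parent_uri) if parent_uri is not None and _local(parent_uri) not in marker_locals else None
        if root == action_root:
            goal = str(next(g.objects(c, CORE["goal"]), "unclassified"))
            if goal not in GOALS:
                goal = "unclassified"
            ont.action_classes[name] = ActionClass(name, None if name == "Action" else parent, goal)  # type: ignore[arg-type]
        elif root == by_local["Equipment"]:
            agency = str(next(g.objects(c, CORE["agency"]), "unspecified"))
            if agency not in AGENCIES:
                agency = "unspecified"
            parent_name = parent if name != "Equipment" else None
            if parent_name == "Datatype":
                parent_name = None
            ont.equipment_classes[name] = EquipmentClass(name, parent_name, agency)  # type: ignore[arg-type]

    for prop in sorted(g.subjects(RDF.type, OWL.DatatypeProperty)):
        if not isinstance(prop, URIRef):
            continue
        name = _local(prop)
        rng = next(g.objects(prop, RDFS.range), None)
        value_kind = _RANGE_TO_VK.get(str(rng), "decimal")
        unit = str(next(g.objects(prop, CORE["unit"]), "")) or parse_unit_suffix(name)
        if not unit and value_kind != "text":
            value_kind = "text"
        ont.scalar_properties[name] = ScalarProperty(name, unit, value_kind)  # type: ignore[arg-type]

    # individuals: templates under Action, equipment individuals under Equipment
    action_class_uris = {by_local.get(n) for n in ont.action_classes if by_local.get(n)}
    equip_class_uris = {by_local.get(n) for n in ont.equipment_classes if by_local.get(n)}
    for subj in sorted(set(g.subjects(RDF.type, None))):
        if not isinstance(subj, URIRef):
            continue
        types = set(g.objects(subj, RDF.type))
        tmpl_classes = types & action_class_uris
        if tmpl_classes:
            tname = _local(subj)
            action_class = _local(sorted(tmpl_classes)[0])
            desc = str(next(g.objects(subj, RDFS.comment), ""))
            params: list[ParameterSpec] = []
            for dir_prop, direction in _PROP_DIRS.items():
                for pnode in g.objects(subj, CORE[dir_prop]):
                    pname = str(next(g.objects(pnode, CORE["parameterName"]), _local(pnode)))
                    pos_lit = next(g.objects(pnode, CORE["parameterPosition"]), None)
                    position = int(str(pos_lit)) if pos_lit is not None else len(params)
                    dt_node = next(g.objects(pnode, CORE["parameterDatatype"]), None)
                    dt_name = _local(dt_node) if dt_node is not None else ""
                    kind = "scalar" if dt_name in ont.scalar_properties else "equipment"
                    params.append(ParameterSpec(pname, direction, DatatypeRef(kind, dt_name), position))  # type: ignore[arg-type]
            params.sort(key=lambda p: (p.position, p.name))
            ont.templates[tname] = ActionTemplate(tname, action_class, tuple(params), desc)
            continue
        eq_classes = types & equip_class_uris
        if eq_classes:
            iname = _local(subj)
            ont.individuals[iname] = EquipmentIndividual(iname, _local(sorted(eq_classes)[0]))

    return ont
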