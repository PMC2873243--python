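"""Rendering and parsing of the two linked interchange files.

A protocol is saved as an XPDL 1.0 document (workflow process, Application
declarations, TypeDeclarations whose ``ExternalReference`` points back at the
ontology) plus an OWL (RDF/XML) individuals file that ``owl:imports`` the
domain ontology and types every equipment individual by its DSO class.  The
DSO file itself is referenced, never rewritten.

Output is canonical — fixed header, lexicographic element ordering, fixed
grid layout coordinates derived from the execution order — so writing the
same models twice produces byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from importlib import resources
from typing import Optional

from lxml import etree
from rdflib import Graph, Namespace, RDF, OWL, URIRef

from .diagnostics import errors_of
from .errors import (
    CycleError,
    LinkageError,
    PathError,
    SchemaError,
    ValidationError,
)
from .ontology import (
    DatatypeRef,
    DomainOntology,
    EquipmentIndividual,
    _dso_ns,
)
from .protocol import (
    ActivityNode,
    Executor,
    Protocol,
    ScalarLiteral,
    Transition,
    Variable,
    execution_order,
)
from .validation import typecheck
from .xpdl import ApplicationDef, DataTypeDecl, FormalParameter, TranslationUnit, sanitize_id

XPDL_NS = "http://www.wfmc.org/2002/XPDL1.0"
_E = "{%s}" % XPDL_NS
NSMAP = {None: XPDL_NS}

#: Fixed package header values: canonical output must not embed wall-clock time.
_CREATED = "2026-01-01 00:00:00"
_VENDOR = "labflow"

_KIND_TO_PARTICIPANT = {"human": "HUMAN", "machine": "RESOURCE", "software": "SYSTEM"}
_PARTICIPANT_TO_KIND = {v: k for k, v in _KIND_TO_PARTICIPANT.items()}

_GRID_X0, _GRID_DX, _GRID_Y = 60, 160, 60
_LITERAL_FIELD_PREFIX = "lit__"


@dataclass
class ProtocolPackage:
    """The two linked documents plus their relative-path linkage."""

    xpdl_document: etree._ElementTree
    individuals_document: Graph
    xpdl_path: str
    individuals_path: str
    dso_location: str


@dataclass
class ReadPackage:
    translation_unit: TranslationUnit
    protocol: Protocol
    individuals: list[EquipmentIndividual]


def _schema() -> etree.XMLSchema:
    ref = resources.files("labflow") / "schemas" / "xpdl_1_0_subset_synthetic.xsd"
    with resources.as_file(ref) as path:
        return etree.XMLSchema(etree.parse(str(path)))


_SCHEMA_CACHE: Optional[etree.XMLSchema] = None


def xpdl_schema() -> etree.XMLSchema:
    global _SCHEMA_CACHE
    if _SCHEMA_CACHE is None:
        _SCHEMA_CACHE = _schema()
    return _SCHEMA_CACHE


def _sub(parent, tag, text=None, **attrs):
    el = etree.SubElement(parent, _E + tag)
    for k, v in attrs.items():
        el.set(k, str(v))
    if text is not None:
        el.text = str(text)
    return el


def _literal_field_id(activity_id: str, param_name: str) -> str:
    return f"{_LITERAL_FIELD_PREFIX}{activity_id}__{param_name}"


def _format_value(value) -> str:
    return repr(value) if isinstance(value, str) else str(value)


def _parse_value(text: str):
    for cast in (int, float):
        try:
            return cast(text)
        except ValueError:
            continue
    if len(text) >= 2 and text[0] == text[-1] == "'":
        return text[1:-1]
    return text


def build_xpdl_document(tu: TranslationUnit, p: Protocol, ont: DomainOntology,
                        dso_location: str, individuals_location: str) -> etree._ElementTree:
    """Construct the XPDL 1.0 tree (deterministic, schema-valid)."""
    pkg_id = sanitize_id(p.name)
    root = etree.Element(_E + "Package", nsmap=NSMAP, Id=pkg_id, Name=p.name)
    header = _sub(root, "PackageHeader")
    _sub(header, "XPDLVersion", "1.0")
    _sub(header, "Vendor", _VENDOR)
    _sub(header, "Created", _CREATED)

    decls = _sub(root, "TypeDeclarations")
    for did in sorted(tu.datatype_decls):
        d = tu.datatype_decls[did]
        td = _sub(decls, "TypeDeclaration", Id=d.id, Name=d.name)
        _sub(td, "ExternalReference", location=d.external_location, xref=d.external_xref)

    if p.executors:
        parts = _sub(root, "Participants")
        for name in sorted(p.executors):
            e = p.executors[name]
            part = _sub(parts, "Participant", Id=sanitize_id(name), Name=name)
            _sub(part, "ParticipantType", Type=_KIND_TO_PARTICIPANT[e.kind])

    apps = _sub(root, "Applications")
    for aid in sorted(tu.applications):
        app = tu.applications[aid]
        ael = _sub(apps, "Application", Id=app.id, Name=app.name)
        if app.description:
            _sub(ael, "Description", app.description)
        if app.formal_params:
            fps = _sub(ael, "FormalParameters")
            for fp in app.formal_params:
                fpe = _sub(fps, "FormalParameter", Id=fp.name, Index=fp.position, Mode=fp.mode)
                dt = _sub(fpe, "DataType")
                _sub(dt, "DeclaredType", Id=fp.datatype_decl)
        ext = _sub(ael, "ExtendedAttributes")
        _sub(ext, "ExtendedAttribute", Name="SourceTemplate", Value=app.source_template)

    procs = _sub(root, "WorkflowProcesses")
    proc = _sub(procs, "WorkflowProcess", Id=pkg_id, Name=p.name)
    _sub(proc, "ProcessHeader")

    # layout / emission order for activities
    try:
        order = execution_order(p)
    except CycleError:
        order = sorted(p.activities)

    fields = _sub(proc, "DataFields")
    for vname in sorted(p.variables):
        v = p.variables[vname]
        fel = _sub(fields, "DataField", Id=sanitize_id(vname), Name=vname, IsArray="FALSE")
        dt = _sub(fel, "DataType")
        _sub(dt, "DeclaredType", Id=tu.decl_for_concept(v.datatype.target).id)
        if v.binding is not None:
            if isinstance(v.binding, ScalarLiteral):
                _sub(fel, "InitialValue", _format_value(v.binding.value))
                ext = _sub(fel, "ExtendedAttributes")
                _sub(ext, "ExtendedAttribute", Name="Unit", Value=v.binding.unit)
            else:
                _sub(fel, "InitialValue", v.binding)
    # inline literals become auto-named data fields
    for aid in order:
        act = p.activities[aid]
        for pname in sorted(act.bindings):
            actual = act.bindings[pname]
            if not isinstance(actual, ScalarLiteral):
                continue
            fid = _literal_field_id(aid, pname)
            fel = _sub(fields, "DataField", Id=fid, Name=fid, IsArray="FALSE")
            dt = _sub(fel, "DataType")
            _sub(dt, "BasicType", Type="STRING" if isinstance(actual.value, str) else "FLOAT")
            _sub(fel, "InitialValue", _format_value(actual.value))
            ext = _sub(fel, "ExtendedAttributes")
            _sub(ext, "ExtendedAttribute", Name="InlineLiteral", Value="TRUE")
            _sub(ext, "ExtendedAttribute", Name="Unit", Value=actual.unit)

    if p.activities:
        acts = _sub(proc, "Activities")
        for i, aid in enumerate(order):
            act = p.activities[aid]
            ael = _sub(acts, "Activity", Id=aid, Name=act.label)
            if act.description:
                _sub(ael, "Description", act.description)
            impl = _sub(ael, "Implementation")
            tool = _sub(impl, "Tool", Id=act.application, Type="APPLICATION")
            app = tu.applications.get(act.application)
            formals = app.formal_params if app is not None else ()
            if formals:
                aps = _sub(tool, "ActualParameters")
                for fp in formals:
                    actual = act.bindings.get(fp.name)
                    if actual is None:
                        _sub(aps, "ActualParameter", "")
                    elif isinstance(actual, ScalarLiteral):
                        _sub(aps, "ActualParameter", _literal_field_id(aid, fp.name))
                    else:
                        _sub(aps, "ActualParameter", actual)
            if act.executor:
                _sub(ael, "Performer", act.executor)
            ext = _sub(ael, "ExtendedAttributes")
            if act.step_label:
                _sub(ext, "ExtendedAttribute", Name="StepLabel", Value=act.step_label)
            _sub(ext, "ExtendedAttribute", Name="XOffset", Value=_GRID_X0 + _GRID_DX * i)
            _sub(ext, "ExtendedAttribute", Name="YOffset", Value=_GRID_Y)

    if p.transitions:
        trans = _sub(proc, "Transitions")
        for tid in sorted(p.transitions):
            t = p.transitions[tid]
            tel = _sub(trans, "Transition", Id=tid, From=t.from_id, To=t.to_id)
            if t.condition is not None:
                _sub(tel, "Condition", t.condition, Type="CONDITION")

    ext = _sub(root, "ExtendedAttributes")
    _sub(ext, "ExtendedAttribute", Name="SourceOntology", Value=tu.source_ontology_iri)
    _sub(ext, "ExtendedAttribute", Name="DsoLocation", Value=dso_location)
    _sub(ext, "ExtendedAttribute", Name="IndividualsLocation", Value=individuals_location)
    return etree.ElementTree(root)


def build_individuals_graph(p: Protocol, ont: DomainOntology) -> Graph:
    """The OWL individuals graph: every ontology individual typed by its DSO
    class; the graph ``owl:imports`` the DSO by IRI."""
    DSO = _dso_ns(ont)
    ind_iri = URIRef(ont.iri + "-individuals")
    triples = [
        (ind_iri, RDF.type, OWL.Ontology),
        (ind_iri, OWL.imports, URIRef(ont.iri)),
    ]
    core_equipment = {"Equipment", "ActiveEntity", "PassiveEntity"}
    CORE = Namespace(ont.core_iri + "#")
    for name in sorted(ont.individuals):
        ind = ont.individuals[name]
        cls = (CORE[ind.equipment_class] if ind.equipment_class in core_equipment
               else DSO[ind.equipment_class])
        triples.append((DSO[name], RDF.type, OWL.NamedIndividual))
        triples.append((DSO[name], RDF.type, cls))
    g = Graph()
    g.bind("owl", OWL)
    g.bind("dso", DSO)
    g.bind("core", CORE)
    for t in sorted(triples):
        g.add(t)
    return g


def write_package(tu: TranslationUnit, p: Protocol, ont: DomainOntology,
                  out_dir, name: Optional[str] = None,
                  dso_location: str = "dso.owl",
                  force: bool = False) -> ProtocolPackage:
    """Write ``<name>.xpdl`` and ``<name>-individuals.owl`` into ``out_dir``.

    Refuses to serialize a protocol with typecheck errors unless ``force``.
    Repeated writes of equal models are byte-identical.
    """
    diags = errors_of(typecheck(p, ont, tu))
    if diags and not force:
        raise ValidationError(
            f"protocol {p.name!r} has {len(diags)} typecheck error(s)", diags)
    out_dir = str(out_dir)
    if not os.path.isdir(out_dir):
        raise PathError(f"output directory does not exist: {out_dir}")
    name = name or sanitize_id(p.name)
    xpdl_path = os.path.join(out_dir, f"{name}.xpdl")
    ind_path = os.path.join(out_dir, f"{name}-individuals.owl")

    doc = build_xpdl_document(tu, p, ont, dso_location, f"{name}-individuals.owl")
    schema = xpdl_schema()
    if not schema.validate(doc):
        raise SchemaError("internal error: emitted XPDL does not validate: "
                          + "; ".join(str(e) for e in schema.error_log))
    graph = build_individuals_graph(p, ont)
    try:
        with open(xpdl_path, "wb") as fh:
            fh.write(etree.tostring(doc, pretty_print=True, xml_declaration=True,
                                    encoding="UTF-8"))
        with open(ind_path, "wb") as fh:
            fh.write(graph.serialize(format="pretty-xml", encoding="utf-8"))
    except OSError as exc:
        raise PathError(str(exc)) from exc
    return ProtocolPackage(doc, graph, xpdl_path, ind_path, dso_location)


def _ext_attrs(el) -> dict[str, str]:
    out = {}
    ext = el.find(_E + "ExtendedAttributes")
    if ext is not None:
        for ea in ext.findall(_E + "ExtendedAttribute"):
            out[ea.get("Name")] = ea.get("Value", "")
    return out


def read_package(xpdl_path, individuals_path, ont: DomainOntology) -> ReadPackage:
    """Parse and re-link a package against an existing domain ontology.

    The XPDL document must validate against the vendored schema
    (:class:`SchemaError` otherwise); every ``ExternalReference`` xref must
    resolve to an ontology concept and every equipment variable binding to an
    individual present in the individuals file (:class:`LinkageError`).
    """
    try:
        doc = etree.parse(str(xpdl_path))
    except (OSError, etree.XMLSyntaxError) as exc:
        raise SchemaError(f"cannot parse XPDL: {exc}") from exc
    schema = xpdl_schema()
    if not schema.validate(doc):
        raise SchemaError("XPDL does not validate: "
                          + "; ".join(str(e) for e in schema.error_log))
    root = doc.getroot()
    pkg_ext = _ext_attrs(root)

    tu = TranslationUnit(source_ontology_iri=pkg_ext.get("SourceOntology", ont.iri))
    known_concepts = ont.datatype_names()
    for td in root.iterfind(f"{_E}TypeDeclarations/{_E}TypeDeclaration"):
        ref = td.find(_E + "ExternalReference")
        xref = ref.get("xref", "")
        if xref not in known_concepts:
            raise LinkageError(f"TypeDeclaration {td.get('Id')!r}: dangling xref {xref!r}")
        tu.datatype_decls[td.get("Id")] = DataTypeDecl(
            id=td.get("Id"), name=td.get("Name", xref),
            external_location=ref.get("location", ""), external_xref=xref)

    for ael in root.iterfind(f"{_E}Applications/{_E}Application"):
        desc = ael.findtext(_E + "Description", "")
        formals = []
        for fpe in ael.iterfind(f"{_E}FormalParameters/{_E}FormalParameter"):
            declared = fpe.find(f"{_E}DataType/{_E}DeclaredType")
            formals.append(FormalParameter(
                name=fpe.get("Id"),
                mode=fpe.get("Mode", "IN"),
                datatype_decl=declared.get("Id") if declared is not None else "",
                position=int(fpe.get("Index", len(formals)))))
        formals.sort(key=lambda f: f.position)
        ext = _ext_attrs(ael)
        app = ApplicationDef(
            id=ael.get("Id"), name=ael.get("Name", ael.get("Id")),
            formal_params=tuple(formals), description=desc,
            source_template=ext.get("SourceTemplate", ael.get("Name", ael.get("Id"))))
        tu.applications[app.id] = app

    # individuals file
    ind_graph = Graph()
    try:
        ind_graph.parse(str(individuals_path), format="xml")
    except Exception as exc:
        raise LinkageError(f"cannot parse individuals file: {exc}") from exc
    individuals: list[EquipmentIndividual] = []
    from .ontology import _local  # local-name helper shared with the loader
    for subj in sorted(set(ind_graph.subjects(RDF.type, None))):
        if not isinstance(subj, URIRef):
            continue
        for cls in ind_graph.objects(subj, RDF.type):
            cname = _local(cls)
            if cname in ont.equipment_classes:
                individuals.append(EquipmentIndividual(_local(subj), cname))
                break
    individual_names = {i.name for i in individuals}

    proc = root.find(f"{_E}WorkflowProcesses/{_E}WorkflowProcess")
    protocol = Protocol(name=proc.get("Name", proc.get("Id")) if proc is not None else root.get("Name"))

    for pel in root.iterfind(f"{_E}Participants/{_E}Participant"):
        ptype = pel.find(_E + "ParticipantType").get("Type")
        name = pel.get("Name", pel.get("Id"))
        protocol.executors[name] = Executor(name, _PARTICIPANT_TO_KIND.get(ptype, "human"))

    decl_concept = {d.id: d.external_xref for d in tu.datatype_decls.values()}
    inline_literals: dict[str, ScalarLiteral] = {}
    if proc is not None:
        for fel in proc.iterfind(f"{_E}DataFields/{_E}DataField"):
            name = fel.get("Name", fel.get("Id"))
            ext = _ext_attrs(fel)
            raw = fel.findtext(_E + "InitialValue")
            if ext.get("InlineLiteral") == "TRUE":
                inline_literals[fel.get("Id")] = ScalarLiteral(
                    _parse_value(raw or ""), ext.get("Unit", ""))
                continue
            declared = fel.find(f"{_E}DataType/{_E}DeclaredType")
            concept = decl_concept.get(declared.get("Id")) if declared is not None else None
            if concept is None:
                raise LinkageError(f"DataField {name!r}: unknown declared type")
            kind = "equipment" if concept in ont.equipment_classes else "scalar"
            binding = None
            if raw is not None:
                if kind == "equipment":
                    if raw not in individual_names:
                        raise LinkageError(
                            f"DataField {name!r}: bound individual {raw!r} missing "
                            f"from individuals file")
                    binding = raw
                else:
                    binding = ScalarLiteral(_parse_value(raw), ext.get("Unit", ""))
            protocol.variables[name] = Variable(name, DatatypeRef(kind, concept), binding)

        for ael in proc.iterfind(f"{_E}Activities/{_E}Activity"):
            aid = ael.get("Id")
            tool = ael.find(f"{_E}Implementation/{_E}Tool")
            app_id = tool.get("Id") if tool is not None else ""
            app = tu.applications.get(app_id)
            bindings: dict = {}
            if tool is not None and app is not None:
                actuals = [a.text or "" for a in
                           tool.iterfind(f"{_E}ActualParameters/{_E}ActualParameter")]
                for fp, text in zip(app.formal_params, actuals):
                    if not text:
                        continue
                    if text in inline_literals:
                        bindings[fp.name] = inline_literals[text]
                    else:
                        bindings[fp.name] = text
            ext = _ext_attrs(ael)
            protocol.activities[aid] = ActivityNode(
                id=aid, label=ael.get("Name", aid), application=app_id,
                bindings=bindings,
                executor=ael.findtext(_E + "Performer"),
                step_label=ext.get("StepLabel"),
                description=ael.findtext(_E + "Description", ""))

        for tel in proc.iterfind(f"{_E}Transitions/{_E}Transition"):
            cond = tel.find(_E + "Condition")
            protocol.transitions[tel.get("Id")] = Transition(
                tel.get("Id"), tel.get("From"), tel.get("To"),
                cond.text if cond is not None else None)

    return ReadPackage(tu, protocol, individuals)
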