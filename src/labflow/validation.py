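"""Static typechecking of a protocol against its ontology and translation unit.

This is where ontology constraints actually bite: every actual parameter of
every activity is checked against the invoked Application's formal-parameter
signature, with equipment compatibility decided by subclass subsumption (a
``Pipette`` variable satisfies an ``Equipment`` slot, never the reverse) and
scalar compatibility by exact property identity — units are never converted,
since a silent ml/ul conversion would reintroduce exactly the ambiguity the
formalization removes.

``typecheck`` is a total function over well-formed inputs: violations come
back as :class:`~labflow.diagnostics.Diagnostic` values, never exceptions.
"""

from __future__ import annotations

from .diagnostics import (
    ARITY_MISMATCH,
    MISSING_UNIT,
    OUT_PARAM_LITERAL,
    TYPE_MISMATCH,
    UNBOUND_INPUT,
    UNCLASSIFIED_GOAL,
    UNKNOWN_APPLICATION,
    UNKNOWN_INDIVIDUAL,
    UNKNOWN_VARIABLE,
    UNREACHABLE_ACTIVITY,
    UNUSED_VARIABLE,
    Diagnostic,
)
from .errors import UnknownClassError
from .ontology import DomainOntology, goal_category
from .protocol import Protocol, ScalarLiteral, reachable_activities
from .xpdl import MODE_TO_DIRECTION, TranslationUnit


def subclass_of(ont: DomainOntology, a: str, b: str) -> bool:
    """True iff ``b`` lies on ``a``'s parent chain (reflexive).

    Works over equipment and action class hierarchies alike.
    """
    if a in ont.equipment_classes:
        chain = ont.equipment_ancestors(a)
    elif a in ont.action_classes:
        chain = ont.action_ancestors(a)
    else:
        raise UnknownClassError(f"unknown class: {a!r}")
    if b not in ont.equipment_classes and b not in ont.action_classes:
        raise UnknownClassError(f"unknown class: {b!r}")
    return b in chain


def typecheck(p: Protocol, ont: DomainOntology, tu: TranslationUnit) -> list[Diagnostic]:
    """All typing findings for a protocol; an empty error set means the
    protocol is fully bound and type-correct.

    Error rules:

    * every IN/INOUT formal parameter is bound (``UNBOUND_INPUT``);
    * binding names are a subset of the formal-parameter names
      (``ARITY_MISMATCH``);
    * OUT/INOUT parameters bind to variables, never literals
      (``OUT_PARAM_LITERAL``);
    * an equipment actual's class is a subclass of the formal class, and a
      scalar actual's property is the formal's property, with its exact unit
      (``TYPE_MISMATCH`` / ``MISSING_UNIT``);
    * referenced applications, variables and individuals exist
      (``UNKNOWN_*``); activities are reachable from the start marker
      (``UNREACHABLE_ACTIVITY``).

    Warnings: variables bound by no activity (``UNUSED_VARIABLE``) and
    templates whose action class has no goal ancestor (``UNCLASSIFIED_GOAL``).
    """
    diags: list[Diagnostic] = []
    used_vars: set[str] = set()

    # variable-level checks
    for vname in sorted(p.variables):
        v = p.variables[vname]
        loc = f"variable/{vname}"
        try:
            concept = ont.resolve(v.datatype)
        except Exception:
            diags.append(Diagnostic(TYPE_MISMATCH, loc,
                                    f"datatype {v.datatype.target!r} unresolvable"))
            continue
        if v.binding is None:
            continue
        if v.datatype.kind == "equipment":
            ind = ont.individuals.get(v.binding) if isinstance(v.binding, str) else None
            if ind is None:
                diags.append(Diagnostic(UNKNOWN_INDIVIDUAL, loc,
                                        f"bound individual {v.binding!r} does not exist"))
            elif not subclass_of(ont, ind.equipment_class, v.datatype.target):
                diags.append(Diagnostic(
                    TYPE_MISMATCH, loc,
                    f"individual {v.binding!r} is a {ind.equipment_class}, "
                    f"not a {v.datatype.target}"))
        else:
            lit = v.binding
            if isinstance(lit, ScalarLiteral):
                if concept.unit and not lit.unit:
                    diags.append(Diagnostic(MISSING_UNIT, loc,
                                            f"literal for {concept.name} lacks a unit "
                                            f"(expected {concept.unit!r})"))
                elif lit.unit != concept.unit:
                    diags.append(Diagnostic(TYPE_MISMATCH, loc,
                                            f"unit {lit.unit!r} != {concept.unit!r}"))

    for aid in sorted(p.activities):
        act = p.activities[aid]
        app = tu.applications.get(act.application)
        if app is None:
            diags.append(Diagnostic(UNKNOWN_APPLICATION, f"activity/{aid}",
                                    f"application {act.application!r} not declared"))
            continue
        formal_names = {fp.name for fp in app.formal_params}
        for bname in sorted(act.bindings):
            if bname not in formal_names:
                diags.append(Diagnostic(
                    ARITY_MISMATCH, f"activity/{aid}/param/{bname}",
                    f"{app.name} has no formal parameter {bname!r}"))
        for fp in app.formal_params:
            loc = f"activity/{aid}/param/{fp.name}"
            actual = act.bindings.get(fp.name)
            if actual is None:
                if MODE_TO_DIRECTION[fp.mode] in ("IN", "IN_OUT"):
                    diags.append(Diagnostic(UNBOUND_INPUT, loc,
                                            f"{fp.mode} parameter {fp.name!r} is unbound"))
                continue
            if isinstance(actual, ScalarLiteral) and fp.mode in ("OUT", "INOUT"):
                diags.append(Diagnostic(OUT_PARAM_LITERAL, loc,
                                        f"{fp.mode} parameter bound to a literal"))
                continue
            decl = tu.datatype_decls.get(fp.datatype_decl)
            concept_name = decl.external_xref if decl is not None else None
            if isinstance(actual, str):
                used_vars.add(actual)
                var = p.variables.get(actual)
                if var is None:
                    diags.append(Diagnostic(UNKNOWN_VARIABLE, loc,
                                            f"variable {actual!r} not declared"))
                    continue
                if concept_name is None:
                    continue
                if concept_name in ont.equipment_classes:
                    if (var.datatype.kind != "equipment"
                            or var.datatype.target not in ont.equipment_classes
                            or not subclass_of(ont, var.datatype.target, concept_name)):
                        diags.append(Diagnostic(
                            TYPE_MISMATCH, loc,
                            f"variable {actual!r} ({var.datatype.target}) is not a "
                            f"{concept_name}"))
                else:
                    if var.datatype.kind != "scalar" or var.datatype.target != concept_name:
                        diags.append(Diagnostic(
                            TYPE_MISMATCH, loc,
                            f"variable {actual!r} ({var.datatype.target}) is not of "
                            f"scalar property {concept_name}"))
            else:  # scalar literal on an IN parameter
                if concept_name is None:
                    continue
                if concept_name in ont.equipment_classes:
                    diags.append(Diagnostic(TYPE_MISMATCH, loc,
                                            "literal bound to an equipment parameter"))
                    continue
                prop = ont.scalar_properties.get(concept_name)
                if prop is None:
                    continue
                if prop.unit and not actual.unit:
                    diags.append(Diagnostic(MISSING_UNIT, loc,
                                            f"literal lacks a unit (expected {prop.unit!r})"))
                elif actual.unit != prop.unit:
                    diags.append(Diagnostic(TYPE_MISMATCH, loc,
                                            f"unit {actual.unit!r} != {prop.unit!r}"))

    reachable = reachable_activities(p)
    for aid in sorted(set(p.activities) - reachable):
        diags.append(Diagnostic(UNREACHABLE_ACTIVITY, f"activity/{aid}",
                                "not reachable from the start marker"))

    for vname in sorted(set(p.variables) - used_vars):
        diags.append(Diagnostic(UNUSED_VARIABLE, f"variable/{vname}",
                                "variable bound by no activity"))

    seen_templates = set()
    for aid in sorted(p.activities):
        app = tu.applications.get(p.activities[aid].application)
        if app is None or app.source_template in seen_templates:
            continue
        seen_templates.add(app.source_template)
        t = ont.templates.get(app.source_template)
        if t is not None and t.action_class in ont.action_classes:
            if goal_category(ont, t.action_class) == "unclassified":
                diags.append(Diagnostic(UNCLASSIFIED_GOAL,
                                        f"template/{t.name}",
                                        f"action class {t.action_class!r} has no goal"))

    return diags
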