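"""Worked example and seeded synthetic generators.

The worked example is a paternity-test protocol fragment: a buccal-swab DNA
extraction whose first three textual steps (cut the swab head into a 1.5 ml
Eppendorf tube, add lysis buffer with a pipette, incubate 30 minutes on a
thermoblock) are formalized end to end — DSO, action templates, typed
variables, activities and transitions.  The step table records, per textual
step, the extracted verbs (action candidates), objects (equipment
candidates) and scalar values; one step may map onto several activity
blocks.

``generate_random_package`` produces reproducible, conformant random
ontologies and typecheck-clean protocols for property tests, plus a
single-defect mutation harness whose manifest records the injected defect —
the ground truth the validator is scored against.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Optional

from lxml import etree
from rdflib import Graph, RDF, URIRef

from . import diagnostics as D
from .ontology import (
    DatatypeRef,
    DomainOntology,
    ParameterSpec,
    ScalarProperty,
)
from .protocol import (
    Protocol,
    ScalarLiteral,
    Variable,
    add_activity,
    add_executor,
    add_transition,
    declare_variable,
    new_protocol,
)
from .xpdl import translate_ontology

eq = DatatypeRef.equipment
sc = DatatypeRef.scalar


# -- paternity-test worked example -------------------------------------------

@dataclass(frozen=True)
class ProtocolStep:
    """One textual protocol step with its extracted ontology concepts."""

    label: str
    text: str
    verbs: tuple[str, ...]
    objects: tuple[str, ...]
    scalars: tuple[tuple[float, str], ...]


#: The three-step fragment of the paternity-test protocol.  Step texts are a
#: synthetic reconstruction written for this fixture; the extracted verbs,
#: objects and scalar values are the fixture's ground truth.
PATERNITY_STEPS: tuple[ProtocolStep, ...] = (
    ProtocolStep(
        "STEP 1",
        "Cut the head of the swab and place it into a 1.5 ml Eppendorf tube.",
        verbs=("Cut", "Add"),
        objects=("SwabHead", "Eppendorf"),
        scalars=((1.5, "ml"),),
    ),
    ProtocolStep(
        "STEP 2",
        "Add the lysis buffer to the tube using a pipette.",
        verbs=("Add",),
        objects=("Eppendorf",),
        scalars=(),
    ),
    ProtocolStep(
        "STEP 3",
        "Incubate the tube in the thermoblock for 30 minutes.",
        verbs=("Incubate",),
        objects=("Thermoblock",),
        scalars=((30, "min"),),
    ),
)


def extracted_verbs() -> set[str]:
    return {v for s in PATERNITY_STEPS for v in s.verbs}


def extracted_objects() -> set[str]:
    return {o for s in PATERNITY_STEPS for o in s.objects}


def extracted_scalars() -> list[tuple[float, str]]:
    """Scalar parameter values printed in the step texts, in step order."""
    return [sv for s in PATERNITY_STEPS for sv in s.scalars]


def build_paternity_dso() -> DomainOntology:
    """The paternity-test domain-specific ontology."""
    ont = DomainOntology.scaffold()
    ont.add_action_class("Cut", "Separation")
    ont.add_action_class("Add", "Combination")
    ont.add_action_class("Incubate", "Transformation")

    ont.add_equipment_class("Swab", "PassiveEntity")
    ont.add_equipment_class("SwabHead", "PassiveEntity")
    ont.add_equipment_class("Eppendorf", "PassiveEntity")
    ont.add_equipment_class("Reagent", "PassiveEntity")
    ont.add_equipment_class("LysisBuffer", "Reagent")
    ont.add_equipment_class("Pipette", "ActiveEntity")
    ont.add_equipment_class("Thermoblock", "ActiveEntity")
    ont.add_equipment_class("Scissors", "ActiveEntity")

    ont.add_scalar_property("volumeQuantity_ul")
    ont.add_scalar_property("volumeQuantity_ml")
    ont.add_scalar_property("durationQuantity_min")

    ont.add_action_template(
        "cut_part_from_object", "Cut",
        [ParameterSpec("tool", "IN", eq("Scissors"), 0),
         ParameterSpec("source", "IN", eq("Swab"), 1),
         ParameterSpec("part", "OUT", eq("SwabHead"), 2)],
        description="Separate a part from an object with a cutting tool.")
    ont.add_action_template(
        "add_labware_to_container", "Add",
        [ParameterSpec("labware", "IN", eq("PassiveEntity"), 0),
         ParameterSpec("container", "IN", eq("Eppendorf"), 1),
         ParameterSpec("capacity", "IN", sc("volumeQuantity_ml"), 2)],
        description="Place a piece of labware into a container of given capacity.")
    ont.add_action_template(
        "add_reagent_to_container", "Add",
        [ParameterSpec("pipette", "IN", eq("Pipette"), 0),
         ParameterSpec("reagent", "IN", eq("Reagent"), 1),
         ParameterSpec("volume", "IN", sc("volumeQuantity_ul"), 2)],
        description="Add a volume of reagent to a container with a pipette.")
    ont.add_action_template(
        "incubate_container", "Incubate",
        [ParameterSpec("device", "IN", eq("Thermoblock"), 0),
         ParameterSpec("container", "IN", eq("Eppendorf"), 1),
         ParameterSpec("duration", "IN", sc("durationQuantity_min"), 2)],
        description="Incubate a container in a heating device for a duration.")

    for name, cls in (("myScissors", "Scissors"), ("mySwab", "Swab"),
                      ("mySwabHead", "SwabHead"), ("myTube", "Eppendorf"),
                      ("myPipette", "Pipette"), ("myLysisBuffer", "LysisBuffer"),
                      ("myThermoblock", "Thermoblock")):
        ont.add_individual(name, cls)
    return ont


#: Lysis-buffer volume for step 2.  The step text does not print a volume;
#: this is a fixture convention (the tube's capacity, in ul), not an
#: extracted value — it never appears in ``extracted_scalars``.
LYSIS_BUFFER_VOLUME_UL = 1500


def build_paternity_example() -> tuple[DomainOntology, Protocol]:
    """The full worked example: DSO plus the three-step protocol.

    The protocol declares the workflow variables ``myPipette`` and
    ``myLysisBuffer`` (typed ``Pipette`` and ``Reagent``) among others, and
    encodes STEP 1 as two activity blocks (cut, then add to tube).
    Typechecks clean against ``translate_ontology`` of the DSO.
    """
    ont = build_paternity_dso()
    tu = translate_ontology(ont)
    p = new_protocol("paternity_test")
    add_executor(p, "technician", "human")

    declare_variable(p, "myScissors", eq("Scissors"), "myScissors", ont=ont)
    declare_variable(p, "mySwab", eq("Swab"), "mySwab", ont=ont)
    declare_variable(p, "mySwabHead", eq("SwabHead"), "mySwabHead", ont=ont)
    declare_variable(p, "myTube", eq("Eppendorf"), "myTube", ont=ont)
    declare_variable(p, "myPipette", eq("Pipette"), "myPipette", ont=ont)
    declare_variable(p, "myLysisBuffer", eq("Reagent"), "myLysisBuffer", ont=ont)
    declare_variable(p, "myThermoblock", eq("Thermoblock"), "myThermoblock", ont=ont)
    declare_variable(p, "tubeCapacity", sc("volumeQuantity_ml"),
                     ScalarLiteral(1.5, "ml"), ont=ont)
    declare_variable(p, "lysisVolume", sc("volumeQuantity_ul"),
                     ScalarLiteral(LYSIS_BUFFER_VOLUME_UL, "ul"), ont=ont)
    declare_variable(p, "incubationTime", sc("durationQuantity_min"),
                     ScalarLiteral(30, "min"), ont=ont)

    app = tu.application_for_template
    add_activity(p, "Cut swab head", app("cut_part_from_object").id,
                 {"tool": "myScissors", "source": "mySwab", "part": "mySwabHead"},
                 executor="technician", step_label="STEP 1", tu=tu,
                 activity_id="cut_swab_head")
    add_activity(p, "Add swab head to tube", app("add_labware_to_container").id,
                 {"labware": "mySwabHead", "container": "myTube",
                  "capacity": "tubeCapacity"},
                 executor="technician", step_label="STEP 1", tu=tu,
                 activity_id="add_swab_head_to_tube")
    add_activity(p, "Add lysis buffer", app("add_reagent_to_container").id,
                 {"pipette": "myPipette", "reagent": "myLysisBuffer",
                  "volume": "lysisVolume"},
                 executor="technician", step_label="STEP 2", tu=tu,
                 activity_id="add_lysis_buffer")
    add_activity(p, "Incubate tube", app("incubate_container").id,
                 {"device": "myThermoblock", "container": "myTube",
                  "duration": "incubationTime"},
                 executor="technician", step_label="STEP 3", tu=tu,
                 activity_id="incubate_tube")

    add_transition(p, "cut_swab_head", "add_swab_head_to_tube")
    add_transition(p, "add_swab_head_to_tube", "add_lysis_buffer")
    add_transition(p, "add_lysis_buffer", "incubate_tube")
    return ont, p


# -- seeded random generator ---------------------------------------------------

@dataclass(frozen=True)
class GeneratorSizes:
    action_classes: int = 5
    equipment_classes: int = 8
    scalar_properties: int = 4
    templates: int = 6
    individuals: int = 8
    activities: int = 6
    executors: int = 2


@dataclass
class GeneratorManifest:
    """Ground truth for one generated package."""

    seed: int
    counts: dict = field(default_factory=dict)
    injected_defect: Optional[dict] = None


#: Defects injected into the ontology; detected by ``validate_ungap_conformance``.
ONTOLOGY_DEFECTS = (
    D.PARAM_TYPE_NOT_DATATYPE,
    D.UNRESOLVED_REFERENCE,
    D.DUPLICATE_POSITION,
    D.NAME_COLLISION,
    D.PARENT_CYCLE,
)

#: Defects injected into the protocol; detected by ``typecheck``.
PROTOCOL_DEFECTS = (
    D.TYPE_MISMATCH,
    D.UNBOUND_INPUT,
    D.ARITY_MISMATCH,
    D.OUT_PARAM_LITERAL,
    D.MISSING_UNIT,
    D.UNKNOWN_APPLICATION,
    D.UNREACHABLE_ACTIVITY,
)

_UNITS = ("ul", "ml", "min", "s", "celsius")


def generate_random_package(seed: int, sizes: Optional[GeneratorSizes] = None,
                            defect: Optional[str] = None
                            ) -> tuple[DomainOntology, Protocol, GeneratorManifest]:
    """A reproducible random DSO + protocol, optionally with one injected defect.

    Without a defect the ontology is conformant and the protocol typechecks
    clean.  With ``defect`` (one of :data:`ONTOLOGY_DEFECTS` or
    :data:`PROTOCOL_DEFECTS`) exactly that violation is present and the
    manifest records it.
    """
    sizes = sizes or GeneratorSizes()
    rng = random.Random(seed)
    ont = DomainOntology.scaffold(iri=f"http://labflow.example.org/ontology/gen{seed}")

    action_names: list[str] = []
    for i in range(sizes.action_classes):
        parent = rng.choice(["Separation", "Transformation", "Combination"] + action_names)
        name = f"Act{i:02d}"
        ont.add_action_class(name, parent)
        action_names.append(name)

    equip_names: list[str] = []
    for i in range(sizes.equipment_classes):
        parent = rng.choice(["Equipment", "ActiveEntity", "PassiveEntity"] + equip_names)
        name = f"Equip{i:02d}"
        ont.add_equipment_class(name, parent)
        equip_names.append(name)

    scalar_names: list[str] = []
    for i in range(sizes.scalar_properties):
        unit = rng.choice(_UNITS)
        name = f"scalar{i:02d}_{unit}"
        ont.add_scalar_property(name, unit)
        scalar_names.append(name)

    template_names: list[str] = []
    for i in range(sizes.templates):
        name = f"tmpl{i:02d}"
        if i == 0 and action_names and equip_names and scalar_names:
            # fixed signature so every defect kind has a deterministic anchor
            params = [
                ParameterSpec("p0", "IN", eq(rng.choice(equip_names)), 0),
                ParameterSpec("p1", "IN", sc(rng.choice(scalar_names)), 1),
                ParameterSpec("p2", "OUT", sc(rng.choice(scalar_names)), 2),
            ]
        else:
            params = []
            for j in range(rng.randint(0, 4)):
                direction = rng.choices(["IN", "OUT", "IN_OUT"], weights=[6, 2, 1])[0]
                if scalar_names and rng.random() < 0.4:
                    dt = sc(rng.choice(scalar_names))
                else:
                    dt = eq(rng.choice(equip_names or ["Equipment"]))
                params.append(ParameterSpec(f"p{j}", direction, dt, j))
        ont.add_action_template(name, rng.choice(action_names or ["Action"]), params)
        template_names.append(name)

    for i in range(sizes.individuals):
        ont.add_individual(f"ind{i:02d}", rng.choice(equip_names or ["Equipment"]))

    tu = translate_ontology(ont)
    p = new_protocol(f"proto_{seed}")
    for i in range(sizes.executors):
        add_executor(p, f"exec{i:02d}", rng.choice(["human", "machine", "software"]))
    executor_names = sorted(p.executors) or [None]

    activity_ids: list[str] = []
    for i in range(sizes.activities if template_names else 0):
        tname = template_names[0] if i == 0 else rng.choice(template_names)
        app = tu.application_for_template(tname)
        bindings: dict = {}
        for fp in app.formal_params:
            vname = f"v{i:02d}_{fp.name}"
            concept = tu.datatype_decls[fp.datatype_decl].external_xref
            if concept in ont.equipment_classes:
                if fp.mode == "OUT":
                    declare_variable(p, vname, eq(concept), ont=ont)
                else:
                    iname = f"auto_ind_{i:02d}_{fp.name}"
                    ont.add_individual(iname, concept)
                    declare_variable(p, vname, eq(concept), iname, ont=ont)
            else:
                prop = ont.scalar_properties[concept]
                if fp.mode == "OUT":
                    declare_variable(p, vname, sc(concept), ont=ont)
                else:
                    value = round(rng.uniform(1, 100), 1)
                    declare_variable(p, vname, sc(concept),
                                     ScalarLiteral(value, prop.unit), ont=ont)
            bindings[fp.name] = vname
        aid = f"a{i:02d}"
        add_activity(p, f"Activity {i}", app.id, bindings,
                     executor=rng.choice(executor_names),
                     step_label=f"STEP {i + 1}", tu=tu, activity_id=aid)
        activity_ids.append(aid)

    for i in range(1, len(activity_ids)):
        add_transition(p, rng.choice(activity_ids[:i]), activity_ids[i])

    manifest = GeneratorManifest(seed=seed, counts={
        "action_classes": len(ont.action_classes),
        "equipment_classes": len(ont.equipment_classes),
        "scalar_properties": len(ont.scalar_properties),
        "templates": len(ont.templates),
        "individuals": len(ont.individuals),
        "activities": len(p.activities),
        "transitions": len(p.transitions),
        "variables": len(p.variables),
    })

    if defect is not None:
        manifest.injected_defect = _inject_defect(ont, p, tu, defect, rng)
    return ont, p, manifest


def _inject_defect(ont: DomainOntology, p: Protocol, tu, defect: str,
                   rng: random.Random) -> dict:
    """Apply one mutation; returns a descriptor with the expected code."""
    scope = "ontology" if defect in ONTOLOGY_DEFECTS else "protocol"
    t0 = ont.templates.get("tmpl00")
    a0 = p.activities.get("a00")

    if defect == D.PARAM_TYPE_NOT_DATATYPE:
        params = list(t0.params)
        params[1] = replace(params[1], datatype=DatatypeRef("scalar", "Act00"))
        ont.templates["tmpl00"] = replace(t0, params=tuple(params))
        location = "template/tmpl00/param/p1"
    elif defect == D.UNRESOLVED_REFERENCE:
        params = list(t0.params)
        params[1] = replace(params[1], datatype=sc("noSuchProperty_ul"))
        ont.templates["tmpl00"] = replace(t0, params=tuple(params))
        location = "template/tmpl00/param/p1"
    elif defect == D.DUPLICATE_POSITION:
        params = list(t0.params)
        params[1] = replace(params[1], position=0)
        ont.templates["tmpl00"] = replace(t0, params=tuple(params))
        location = "template/tmpl00"
    elif defect == D.NAME_COLLISION:
        clash = sorted(n for n in ont.equipment_classes if n.startswith("Equip"))[0]
        ont.scalar_properties[clash] = ScalarProperty(clash, "ul", "decimal")
        location = f"datatype/{clash}"
    elif defect == D.PARENT_CYCLE:
        a, b = ont.action_classes["Act00"], ont.action_classes["Act01"]
        ont.action_classes["Act00"] = replace(a, parent="Act01")
        ont.action_classes["Act01"] = replace(b, parent="Act00")
        location = "action_class/Act00"
    elif defect == D.TYPE_MISMATCH:
        ont.add_equipment_class("MismatchClass", "Equipment")
        ont.add_individual("mismatch_ind", "MismatchClass")
        declare_variable(p, "mismatch_var", eq("MismatchClass"), "mismatch_ind", ont=ont)
        a0.bindings["p0"] = "mismatch_var"
        location = "activity/a00/param/p0"
    elif defect == D.UNBOUND_INPUT:
        del a0.bindings["p0"]
        location = "activity/a00/param/p0"
    elif defect == D.ARITY_MISMATCH:
        a0.bindings["ghost_param"] = a0.bindings["p0"]
        location = "activity/a00/param/ghost_param"
    elif defect == D.OUT_PARAM_LITERAL:
        prop = ont.scalar_properties[
            tu.datatype_decls[
                tu.application_for_template("tmpl00").formal_params[2].datatype_decl
            ].external_xref]
        a0.bindings["p2"] = ScalarLiteral(1.0, prop.unit)
        location = "activity/a00/param/p2"
    elif defect == D.MISSING_UNIT:
        concept = tu.datatype_decls[
            tu.application_for_template("tmpl00").formal_params[1].datatype_decl
        ].external_xref
        p.variables["nounit_var"] = Variable("nounit_var", sc(concept),
                                             ScalarLiteral(5.0, ""))
        a0.bindings["p1"] = "nounit_var"
        location = "variable/nounit_var"
    elif defect == D.UNKNOWN_APPLICATION:
        a0.application = "no_such_application"
        location = "activity/a00"
    elif defect == D.UNREACHABLE_ACTIVITY:
        app = tu.application_for_template("tmpl00")
        add_activity(p, "Orphan", app.id, dict(a0.bindings), tu=tu,
                     activity_id="z_orphan")
        add_transition(p, "z_orphan", "z_orphan")
        location = "activity/z_orphan"
    else:
        raise ValueError(f"unknown defect: {defect!r}")
    return {"code": defect, "scope": scope, "location": location}


# -- linkage corruption (operates on written package files) --------------------

LINKAGE_DEFECTS = ("dangling_xref", "missing_individual")


def corrupt_package_linkage(xpdl_path, individuals_path, mode: str) -> str:
    """Break one cross-file link in a written package; returns the broken name.

    ``dangling_xref`` retargets the first TypeDeclaration's ExternalReference
    at a concept that exists nowhere; ``missing_individual`` deletes from the
    OWL file the first individual a variable is bound to.
    """
    if mode == "dangling_xref":
        doc = etree.parse(str(xpdl_path))
        ns = {"x": "http://www.wfmc.org/2002/XPDL1.0"}
        ref = doc.find(".//x:TypeDeclaration/x:ExternalReference", ns)
        ref.set("xref", "GhostConcept")
        doc.write(str(xpdl_path), xml_declaration=True, encoding="UTF-8")
        return "GhostConcept"
    if mode == "missing_individual":
        doc = etree.parse(str(xpdl_path))
        ns = {"x": "http://www.wfmc.org/2002/XPDL1.0"}
        victim = None
        for fel in doc.findall(".//x:DataField", ns):
            iv = fel.find("x:InitialValue", ns)
            ext = fel.findall(".//x:ExtendedAttribute", ns)
            inline = any(e.get("Name") == "InlineLiteral" for e in ext)
            unit = any(e.get("Name") == "Unit" for e in ext)
            if iv is not None and not inline and not unit:
                victim = iv.text
                break
        if victim is None:
            raise ValueError("no equipment binding to corrupt")
        g = Graph()
        g.parse(str(individuals_path), format="xml")
        targets = [s for s in g.subjects(RDF.type, None)
                   if isinstance(s, URIRef) and str(s).endswith("#" + victim)]
        for s in targets:
            g.remove((s, None, None))
        with open(individuals_path, "wb") as fh:
            fh.write(g.serialize(format="pretty-xml", encoding="utf-8"))
        return victim
    raise ValueError(f"unknown linkage defect: {mode!r}")
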