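"""Ontology model: OWL round-trips, goal inheritance, conformance checking."""

import io
import random

import pytest

from labflow.diagnostics import errors_of
from labflow.errors import (
    DuplicateNameError,
    ParseError,
    ScaffoldError,
    UnknownClassError,
    UnknownTypeError,
)
from labflow.fixtures import (
    ONTOLOGY_DEFECTS,
    build_paternity_dso,
    generate_random_package,
)
from labflow.ontology import (
    ActionClass,
    DatatypeRef,
    DomainOntology,
    ParameterSpec,
    goal_category,
    load_domain_ontology,
    parse_unit_suffix,
    save_domain_ontology,
    validate_ungap_conformance,
)


def roundtrip(ont, format="rdfxml"):
    buf = io.BytesIO()
    save_domain_ontology(ont, buf, format=format)
    return load_domain_ontology(io.BytesIO(buf.getvalue()),
                                format="turtle" if format == "turtle" else "xml")


class TestLoadSave:
    def test_paternity_dso_equipment_classes(self):
        ont = roundtrip(build_paternity_dso())
        assert {"Thermoblock", "Swab", "Pipette"} <= set(ont.equipment_classes)

    @pytest.mark.parametrize("format", ["rdfxml", "turtle"])
    def test_roundtrip_semantic_identity(self, format):
        ont = build_paternity_dso()
        assert roundtrip(ont, format) == ont

    def test_scaffold_only_ontology_is_empty(self):
        ont = roundtrip(DomainOntology.scaffold())
        assert ont.templates == {} and ont.individuals == {}
        assert set(ont.action_classes) == {"Action", "Separation",
                                           "Transformation", "Combination"}

    @pytest.mark.parametrize("seed", range(5))
    def test_generated_roundtrip_counts_match_manifest(self, seed):
        ont, _, manifest = generate_random_package(seed)
        loaded = roundtrip(ont)
        assert loaded == ont
        assert len(loaded.templates) == manifest.counts["templates"]
        assert len(loaded.individuals) == manifest.counts["individuals"]
        assert len(loaded.equipment_classes) == manifest.counts["equipment_classes"]

    def test_malformed_document_raises_parse_error(self):
        with pytest.raises(ParseError):
            load_domain_ontology(io.BytesIO(b"<<< not rdf"), format="xml")

    def test_missing_scaffold_raises(self):
        # a well-formed RDF graph that simply lacks Action/Equipment/Datatype
        data = b"""<?xml version="1.0"?>
        <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#"
                 xmlns:owl="http://www.w3.org/2002/07/owl#">
          <owl:Class rdf:about="http://x.org/ont#Unrelated"/>
        </rdf:RDF>"""
        with pytest.raises(ScaffoldError):
            load_domain_ontology(io.BytesIO(data), format="xml")


class TestGoalCategory:
    def test_fixture_add_is_combination(self):
        ont = build_paternity_dso()
        assert goal_category(ont, "Add") == "combination"
        assert goal_category(ont, "Cut") == "separation"

    def test_root_action_is_unclassified(self):
        ont = DomainOntology.scaffold()
        assert goal_category(ont, "Action") == "unclassified"

    def test_matches_bruteforce_ancestor_scan_on_random_hierarchies(self):
        # oracle: linear walk up the explicit parent chain
        rng = random.Random(20260927)
        for _ in range(1000):
            ont = DomainOntology.scaffold()
            names = []
            for i in range(rng.randint(1, 15)):
                parent = rng.choice(["Action", "Separation", "Transformation",
                                     "Combination"] + names)
                name = f"C{i}"
                goal = rng.choice(["unclassified"] * 3
                                  + ["separation", "transformation", "combination"])
                ont.action_classes[name] = ActionClass(name, parent, goal)
                names.append(name)
            probe = rng.choice(names)

            def oracle(n):
                while n is not None:
                    ac = ont.action_classes[n]
                    if ac.goal != "unclassified":
                        return ac.goal
                    n = ac.parent
                return "unclassified"

            assert goal_category(ont, probe) == oracle(probe)


class TestMutation:
    def test_unit_suffix_parsing(self):
        assert parse_unit_suffix("volumeQuantity_ul") == "ul"
        assert parse_unit_suffix("durationQuantity_min") == "min"
        assert parse_unit_suffix("plainName") == ""
        assert parse_unit_suffix("notAUnit_xyz") == ""

    def test_add_template_idempotent(self):
        ont = build_paternity_dso()
        before = ont.copy()
        ont.add_action_template(
            "add_reagent_to_container", "Add",
            ont.templates["add_reagent_to_container"].params,
            ont.templates["add_reagent_to_container"].description)
        assert ont == before

    def test_add_template_conflicting_payload_rejected(self):
        ont = build_paternity_dso()
        with pytest.raises(DuplicateNameError):
            ont.add_action_template("add_reagent_to_container", "Cut")

    def test_add_template_unknown_type_rejected(self):
        ont = build_paternity_dso()
        with pytest.raises(UnknownTypeError):
            ont.add_action_template(
                "bad", "Add",
                [ParameterSpec("x", "IN", DatatypeRef.equipment("NoSuch"), 0)])

    def test_empty_params_template_valid(self):
        ont = build_paternity_dso()
        ont.add_action_template("noop_action", "Add")
        assert ont.templates["noop_action"].params == ()

    def test_add_individual_counting(self):
        ont = build_paternity_dso()
        n0 = len(ont.individuals)
        for i in range(7):
            ont.add_individual(f"extra{i}", "Pipette")
        assert len(ont.individuals) == n0 + 7

    def test_add_individual_unknown_class(self):
        ont = build_paternity_dso()
        with pytest.raises(UnknownClassError):
            ont.add_individual("ghost", "NoSuchClass")


class TestConformance:
    def test_paternity_dso_conformant(self):
        report = validate_ungap_conformance(build_paternity_dso())
        assert report.conformant
        assert errors_of(report.findings) == []

    def test_param_typed_outside_datatype_flagged(self):
        ont = build_paternity_dso()
        # an action class is not a member of the Datatype union
        ont.templates["bad"] = type(ont.templates["cut_part_from_object"])(
            "bad", "Add",
            (ParameterSpec("x", "IN", DatatypeRef.equipment("Cut"), 0),), "")
        codes = {f.code for f in errors_of(validate_ungap_conformance(ont).findings)}
        assert codes == {"PARAM_TYPE_NOT_DATATYPE"}

    @pytest.mark.parametrize("defect", ONTOLOGY_DEFECTS)
    @pytest.mark.parametrize("seed", range(10))
    def test_seeded_corruptions_detected_exactly(self, seed, defect):
        """50 single-mutation corruptions: the checker reports exactly the
        injected violation (sound and complete vs the defect catalogue)."""
        ont, _, manifest = generate_random_package(seed, defect=defect)
        report = validate_ungap_conformance(ont)
        codes = {f.code for f in errors_of(report.findings)}
        assert codes == {manifest.injected_defect["code"]}
        assert not report.conformant

    @pytest.mark.parametrize("seed", range(10))
    def test_unmutated_generated_dsos_clean(self, seed):
        ont, _, _ = generate_random_package(seed)
        assert validate_ungap_conformance(ont).conformant
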