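"""Ontology-to-XPDL transformation: bijection, mode mapping, determinism."""

import random

import pytest

from labflow.errors import ConformanceError, MissingDeclarationError, UnknownTypeError
from labflow.fixtures import build_paternity_dso, generate_random_package
from labflow.ontology import ActionTemplate, DatatypeRef, ParameterSpec
from labflow.xpdl import (
    DIRECTION_TO_MODE,
    assign_ids,
    datatype_to_xpdl,
    sanitize_id,
    template_to_application,
    translate_ontology,
)


class TestDatatypeDecls:
    def test_equipment_declaration_is_external_reference(self):
        ont = build_paternity_dso()
        decl = datatype_to_xpdl(DatatypeRef.equipment("Pipette"), "dso.owl", ont)
        assert decl.external_xref == "Pipette"
        assert decl.external_location == "dso.owl"

    def test_translating_same_ref_twice_is_identical(self):
        ont = build_paternity_dso()
        ref = DatatypeRef.scalar("volumeQuantity_ul")
        assert datatype_to_xpdl(ref, "dso.owl", ont) == datatype_to_xpdl(ref, "dso.owl", ont)

    def test_unknown_ref_rejected(self):
        with pytest.raises(UnknownTypeError):
            datatype_to_xpdl(DatatypeRef.equipment("Ghost"), "dso.owl",
                             build_paternity_dso())

    @pytest.mark.parametrize("seed", range(5))
    def test_one_declaration_per_datatype_member(self, seed):
        ont, _, _ = generate_random_package(seed)
        tu = translate_ontology(ont)
        expected = set(ont.equipment_classes) | set(ont.scalar_properties)
        assert {d.external_xref for d in tu.datatype_decls.values()} == expected
        assert len(tu.datatype_decls) == len(expected)


class TestApplications:
    def test_add_reagent_to_container_three_in_params(self, paternity):
        _, _, tu = paternity
        app = tu.application_for_template("add_reagent_to_container")
        assert len(app.formal_params) == 3
        assert all(fp.mode == "IN" for fp in app.formal_params)
        assert [fp.name for fp in app.formal_params] == ["pipette", "reagent", "volume"]

    def test_zero_parameter_template(self):
        ont = build_paternity_dso()
        ont.add_action_template("noop", "Add")
        tu = translate_ontology(ont)
        assert tu.application_for_template("noop").formal_params == ()

    def test_mode_multiset_matches_directions(self):
        """Random templates with (a,b,c) IN/OUT/IN_OUT params map to the
        {INxa, OUTxb, INOUTxc} mode multiset (counting oracle)."""
        rng = random.Random(7)
        ont = build_paternity_dso()
        tu = translate_ontology(ont)
        for trial in range(50):
            counts = {"IN": rng.randint(0, 3), "OUT": rng.randint(0, 3),
                      "IN_OUT": rng.randint(0, 3)}
            params, pos = [], 0
            for direction, n in counts.items():
                for _ in range(n):
                    params.append(ParameterSpec(f"p{pos}", direction,
                                                DatatypeRef.equipment("Pipette"), pos))
                    pos += 1
            t = ActionTemplate(f"t{trial}", "Add", tuple(params))
            app = template_to_application(t, tu.datatype_decls)
            got = sorted(fp.mode for fp in app.formal_params)
            want = sorted(DIRECTION_TO_MODE[d] for d, n in counts.items()
                          for _ in range(n))
            assert got == want

    def test_missing_declaration_rejected(self):
        t = ActionTemplate("t", "Add",
                           (ParameterSpec("x", "IN", DatatypeRef.equipment("Pipette"), 0),))
        with pytest.raises(MissingDeclarationError):
            template_to_application(t, {})


class TestTranslateOntology:
    def test_fixture_add_class_yields_two_applications(self, paternity):
        ont, _, tu = paternity
        add_apps = [a for a in tu.applications.values()
                    if ont.templates[a.source_template].action_class == "Add"]
        assert len(add_apps) == 2
        assert {a.name for a in add_apps} == {"add_labware_to_container",
                                              "add_reagent_to_container"}

    def test_empty_ontology_yields_no_applications(self):
        from labflow.ontology import DomainOntology
        tu = translate_ontology(DomainOntology.scaffold())
        assert tu.applications == {}

    @pytest.mark.parametrize("seed", range(20))
    def test_bijection_templates_to_applications(self, seed):
        ont, _, _ = generate_random_package(seed)
        tu = translate_ontology(ont)
        assert len(tu.applications) == len(ont.templates)
        assert {a.source_template for a in tu.applications.values()} == set(ont.templates)
        for app in tu.applications.values():
            t = ont.templates[app.source_template]
            assert len(app.formal_params) == len(t.params)
            assert [fp.mode for fp in app.formal_params] == [
                DIRECTION_TO_MODE[p.direction]
                for p in sorted(t.params, key=lambda p: p.position)]

    def test_deterministic_output(self):
        ont, _, _ = generate_random_package(11)
        assert translate_ontology(ont) == translate_ontology(ont)

    def test_nonconformant_input_refused(self):
        ont, _, _ = generate_random_package(2, defect="PARAM_TYPE_NOT_DATATYPE")
        with pytest.raises(ConformanceError):
            translate_ontology(ont)


class TestIds:
    def test_sanitize_strips_punctuation(self):
        assert sanitize_id("add reagent (ul)!") == "add_reagent_ul"

    def test_collisions_resolved_lexicographically(self):
        ids = assign_ids(["a b", "a-b", "a_b"])
        assert sorted(ids.values()) == ["a_b", "a_b_2", "a_b_3"]
        assert len(set(ids.values())) == 3
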