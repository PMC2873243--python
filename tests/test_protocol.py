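"""Protocol builder: variables, activities, transitions, execution order."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from labflow.errors import (
    CycleError,
    UnknownActivityError,
    UnknownApplicationError,
    UnknownIndividualError,
    UnknownVariableError,
)
from labflow.fixtures import build_paternity_dso, build_paternity_example
from labflow.ontology import DatatypeRef
from labflow.protocol import (
    ScalarLiteral,
    add_activity,
    add_transition,
    declare_variable,
    execution_order,
    new_protocol,
    reachable_activities,
)
from labflow.xpdl import translate_ontology


@pytest.fixture()
def session():
    ont = build_paternity_dso()
    return ont, translate_ontology(ont)


class TestBuilder:
    def test_new_protocol_empty(self):
        p = new_protocol("paternity_test")
        assert p.activities == {} and p.variables == {}

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            new_protocol("  ")

    def test_same_name_protocols_independent(self):
        a, b = new_protocol("x"), new_protocol("x")
        a.variables["v"] = None
        assert b.variables == {}

    def test_declare_equipment_variable_bound(self, session):
        ont, _ = session
        p = new_protocol("p")
        declare_variable(p, "myPipette", DatatypeRef.equipment("Pipette"),
                         "myPipette", ont=ont)
        assert p.variables["myPipette"].binding == "myPipette"

    def test_declare_scalar_variable_unbound(self, session):
        ont, _ = session
        p = new_protocol("p")
        declare_variable(p, "volume", DatatypeRef.scalar("volumeQuantity_ul"), ont=ont)
        assert p.variables["volume"].binding is None

    def test_binding_missing_individual_rejected(self, session):
        ont, _ = session
        p = new_protocol("p")
        with pytest.raises(UnknownIndividualError):
            declare_variable(p, "v", DatatypeRef.equipment("Pipette"),
                             "ghostPipette", ont=ont)

    def test_activity_with_undeclared_variable_rejected(self, session):
        ont, tu = session
        p = new_protocol("p")
        app = tu.application_for_template("add_reagent_to_container")
        with pytest.raises(UnknownVariableError):
            add_activity(p, "Add", app.id, {"pipette": "nowhere"}, tu=tu)

    def test_unknown_application_rejected(self, session):
        _, tu = session
        with pytest.raises(UnknownApplicationError):
            add_activity(new_protocol("p"), "X", "no_such_app", tu=tu)

    def test_one_step_two_activity_blocks(self):
        _, p = build_paternity_example()
        step1 = [a for a in p.activities.values() if a.step_label == "STEP 1"]
        assert len(step1) == 2

    def test_transition_to_unknown_activity_rejected(self, session):
        with pytest.raises(UnknownActivityError):
            add_transition(new_protocol("p"), "a", "b")


def _chain_protocol(n, session, conditions=None):
    ont, tu = session
    p = new_protocol("chain")
    app = tu.application_for_template("cut_part_from_object")
    declare_variable(p, "s", DatatypeRef.equipment("Scissors"), "myScissors", ont=ont)
    declare_variable(p, "w", DatatypeRef.equipment("Swab"), "mySwab", ont=ont)
    declare_variable(p, "h", DatatypeRef.equipment("SwabHead"), ont=ont)
    for i in range(n):
        add_activity(p, f"act {i}", app.id,
                     {"tool": "s", "source": "w", "part": "h"},
                     tu=tu, activity_id=f"n{i:03d}")
    return p


class TestExecutionOrder:
    def test_paternity_order_matches_step_order(self, paternity):
        _, p, _ = paternity
        order = execution_order(p)
        assert order == ["cut_swab_head", "add_swab_head_to_tube",
                         "add_lysis_buffer", "incubate_tube"]
        labels = [p.activities[a].step_label for a in order]
        assert labels == ["STEP 1", "STEP 1", "STEP 2", "STEP 3"]

    def test_empty_protocol_empty_order(self):
        assert execution_order(new_protocol("p")) == []

    def test_linear_chain_out_degree(self, session):
        p = _chain_protocol(3, session)
        add_transition(p, "n000", "n001")
        add_transition(p, "n001", "n002")
        assert len(p.transitions) == 2
        assert execution_order(p) == ["n000", "n001", "n002"]

    def test_unconditional_cycle_raises(self, session):
        p = _chain_protocol(2, session)
        add_transition(p, "n000", "n001")
        add_transition(p, "n001", "n000")
        with pytest.raises(CycleError):
            execution_order(p)

    def test_conditional_back_edge_loop_accepted(self, session):
        # loops are workflow-level constructs: a conditional back-edge is legal
        p = _chain_protocol(3, session)
        add_transition(p, "n000", "n001")
        add_transition(p, "n001", "n002")
        add_transition(p, "n002", "n001", condition="repeat needed")
        assert execution_order(p) == ["n000", "n001", "n002"]

    def test_random_dags_yield_valid_topological_sorts(self, session):
        """Oracle: edge-by-edge precedence check over 1000 random DAGs."""
        rng = random.Random(424242)
        for _ in range(1000):
            n = rng.randint(1, 12)
            p = _chain_protocol(n, session)
            ids = sorted(p.activities)
            for _ in range(rng.randint(0, 2 * n)):
                i, j = sorted(rng.sample(range(n), 2)) if n > 1 else (0, 0)
                if i != j:
                    add_transition(p, ids[i], ids[j])
            order = execution_order(p)
            assert sorted(order) == ids
            pos = {a: k for k, a in enumerate(order)}
            for t in p.transitions.values():
                assert pos[t.from_id] < pos[t.to_id]

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_order_deterministic(self, seed):
        rng = random.Random(seed)
        ont = build_paternity_dso()
        session = (ont, translate_ontology(ont))
        n = rng.randint(1, 8)
        p = _chain_protocol(n, session)
        ids = sorted(p.activities)
        for _ in range(rng.randint(0, n)):
            if n > 1:
                i, j = sorted(rng.sample(range(n), 2))
                add_transition(p, ids[i], ids[j])
        assert execution_order(p) == execution_order(p)


class TestReachability:
    def test_matches_bruteforce_bfs(self, session):
        rng = random.Random(99)
        for _ in range(200):
            n = rng.randint(1, 10)
            p = _chain_protocol(n, session)
            ids = sorted(p.activities)
            for _ in range(rng.randint(0, 2 * n)):
                a, b = rng.choice(ids), rng.choice(ids)
                if a != b:
                    add_transition(p, a, b)
            # oracle: BFS from the implicit start marker (in-degree-0 nodes)
            succ = {a: set() for a in ids}
            indeg = {a: 0 for a in ids}
            for t in p.transitions.values():
                succ[t.from_id].add(t.to_id)
                indeg[t.to_id] += 1
            frontier = [a for a in ids if indeg[a] == 0]
            seen = set()
            while frontier:
                x = frontier.pop()
                if x in seen:
                    continue
                seen.add(x)
                frontier.extend(succ[x])
            assert reachable_activities(p) == seen
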