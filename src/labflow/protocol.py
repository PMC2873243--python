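"""Protocol construction: typed variables, activities, transitions, executors.

A :class:`Protocol` is a workflow process.  Variables are typed by the
ontology's ``Datatype`` union and optionally bound — equipment variables to
an ontology individual, scalar variables to a literal value with a unit.
Each activity invokes one XPDL Application with actual-parameter bindings
(variable names, or inline scalar literals which the serializer normalizes
into auto-named data fields).  Transitions order activities; conditions are
opaque strings.  The protocol has an implicit single start marker feeding
every activity without an incoming transition and an implicit end marker.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Union

from .errors import (
    CycleError,
    DuplicateNameError,
    UnknownActivityError,
    UnknownApplicationError,
    UnknownIndividualError,
    UnknownVariableError,
)
from .ontology import DatatypeRef, DomainOntology
from .xpdl import TranslationUnit, sanitize_id

ExecutorKind = Literal["human", "machine", "software"]


@dataclass(frozen=True)
class ScalarLiteral:
    """An inline scalar actual parameter, e.g. ``ScalarLiteral(1.5, "ml")``."""

    value: Union[int, float, str]
    unit: str = ""


#: What an actual parameter can be bound to: a variable name or a literal.
Actual = Union[str, ScalarLiteral]


@dataclass(frozen=True)
class Variable:
    name: str
    datatype: DatatypeRef
    binding: Optional[Actual] = None  # individual name (equipment) or literal (scalar)


@dataclass(frozen=True)
class Executor:
    """A participant able to carry out activities: a person, a machine, or
    a piece of software."""

    name: str
    kind: ExecutorKind = "human"


@dataclass
class ActivityNode:
    id: str
    label: str
    application: str  # ApplicationDef id
    bindings: dict[str, Actual] = field(default_factory=dict)
    executor: Optional[str] = None
    step_label: Optional[str] = None
    description: str = ""

    def __eq__(self, other):
        if not isinstance(other, ActivityNode):
            return NotImplemented
        return (self.id, self.label, self.application, self.bindings,
                self.executor, self.step_label, self.description) == (
                other.id, other.label, other.application, other.bindings,
                other.executor, other.step_label, other.description)


@dataclass(frozen=True)
class Transition:
    id: str
    from_id: str
    to_id: str
    condition: Optional[str] = None


@dataclass
class Protocol:
    name: str
    variables: dict[str, Variable] = field(default_factory=dict)
    activities: dict[str, ActivityNode] = field(default_factory=dict)
    transitions: dict[str, Transition] = field(default_factory=dict)
    executors: dict[str, Executor] = field(default_factory=dict)

    def __eq__(self, other):
        if not isinstance(other, Protocol):
            return NotImplemented
        return (self.name == other.name
                and self.variables == other.variables
                and self.activities == other.activities
                and self.transitions == other.transitions
                and self.executors == other.executors)


def new_protocol(name: str) -> Protocol:
    """An empty protocol (implicit start/end markers, no activities)."""
    if not name or not name.strip():
        raise ValueError("protocol name must be non-empty")
    return Protocol(name=name)


def declare_variable(p: Protocol, name: str, datatype: DatatypeRef,
                     binding: Optional[Actual] = None, *,
                     ont: DomainOntology) -> Protocol:
    """Declare a typed workflow variable, optionally bound.

    Equipment bindings must name an existing ontology individual; scalar
    bindings are literals carrying the unit of their scalar property.
    """
    ont.resolve(datatype)  # UnknownTypeError if unresolvable
    if binding is not None and datatype.kind == "equipment":
        if not isinstance(binding, str):
            raise TypeError("equipment variables bind to an individual name")
        if binding not in ont.individuals:
            raise UnknownIndividualError(f"unknown individual: {binding!r}")
    if binding is not None and datatype.kind == "scalar":
        if isinstance(binding, (int, float)):
            binding = ScalarLiteral(binding, ont.resolve(datatype).unit)
        if not isinstance(binding, ScalarLiteral):
            raise TypeError("scalar variables bind to a ScalarLiteral")
    v = Variable(name, datatype, binding)
    existing = p.variables.get(name)
    if existing is not None:
        if existing != v:
            raise DuplicateNameError(f"variable {name!r} already declared differently")
        return p
    p.variables[name] = v
    return p


def add_executor(p: Protocol, name: str, kind: ExecutorKind = "human") -> Protocol:
    e = Executor(name, kind)
    existing = p.executors.get(name)
    if existing is not None and existing != e:
        raise DuplicateNameError(f"executor {name!r} already declared differently")
    p.executors[name] = e
    return p


def add_activity(p: Protocol, label: str, application: str,
                 bindings: Optional[Mapping[str, Actual]] = None,
                 executor: Optional[str] = None,
                 step_label: Optional[str] = None,
                 description: str = "", *,
                 tu: TranslationUnit,
                 activity_id: Optional[str] = None) -> Protocol:
    """Append an activity invoking ``application`` with actual parameters.

    ``bindings`` maps formal-parameter names to declared variable names or
    inline :class:`ScalarLiteral` values.  Several activities may share one
    ``step_label`` (one textual protocol step can need more than one block).
    """
    if application not in tu.applications:
        raise UnknownApplicationError(f"unknown application: {application!r}")
    bindings = dict(bindings or {})
    for pname, actual in bindings.items():
        if isinstance(actual, str) and actual not in p.variables:
            raise UnknownVariableError(
                f"activity {label!r} binds undeclared variable {actual!r}")
    if executor is not None and executor not in p.executors:
        raise UnknownVariableError(f"unknown executor: {executor!r}")
    if activity_id is None:
        base = sanitize_id(label)
        activity_id, k = base, 2
        while activity_id in p.activities:
            activity_id = f"{base}_{k}"
            k += 1
    elif activity_id in p.activities:
        raise DuplicateNameError(f"activity id {activity_id!r} already used")
    p.activities[activity_id] = ActivityNode(
        id=activity_id, label=label, application=application,
        bindings=bindings, executor=executor, step_label=step_label,
        description=description)
    return p


def add_transition(p: Protocol, from_id: str, to_id: str,
                   condition: Optional[str] = None,
                   transition_id: Optional[str] = None) -> Protocol:
    """Add a control-flow edge.  Splits (out-degree > 1) express parallelism
    or choice depending on conditions; back-edges (loops) are accepted."""
    for endpoint in (from_id, to_id):
        if endpoint not in p.activities:
            raise UnknownActivityError(f"unknown activity: {endpoint!r}")
    if transition_id is None:
        n = 1
        while f"t{n}" in p.transitions:
            n += 1
        transition_id = f"t{n}"
    elif transition_id in p.transitions:
        raise DuplicateNameError(f"transition id {transition_id!r} already used")
    p.transitions[transition_id] = Transition(transition_id, from_id, to_id, condition)
    return p


def execution_order(p: Protocol) -> list[str]:
    """A deterministic topological order of activity ids.

    The order respects every transition when the full graph is acyclic;
    otherwise conditional edges (which may legitimately form loops) are
    dropped and the unconditional subgraph must be acyclic, else
    :class:`CycleError`.  Ties are broken by activity id.
    """
    for conditional_ok in (True, False):
        edges = [(t.from_id, t.to_id) for t in p.transitions.values()
                 if conditional_ok or t.condition is None]
        order = _topo_sort(set(p.activities), edges)
        if order is not None:
            return order
    raise CycleError(f"protocol {p.name!r}: unconditional transition cycle")


def _topo_sort(nodes: set[str], edges: list[tuple[str, str]]) -> Optional[list[str]]:
    """Kahn's algorithm with a min-heap tie-break; None if cyclic."""
    indeg = {n: 0 for n in nodes}
    succ: dict[str, list[str]] = {n: [] for n in nodes}
    for a, b in edges:
        succ[a].append(b)
        indeg[b] += 1
    heap = [n for n in nodes if indeg[n] == 0]
    heapq.heapify(heap)
    out: list[str] = []
    while heap:
        n = heapq.heappop(heap)
        out.append(n)
        for m in sorted(succ[n]):
            indeg[m] -= 1
            if indeg[m] == 0:
                heapq.heappush(heap, m)
    return out if len(out) == len(nodes) else None


def reachable_activities(p: Protocol) -> set[str]:
    """Activities reachable from the start marker, which feeds every
    activity with no incoming transition (over all edges, conditional
    included)."""
    has_incoming = {t.to_id for t in p.transitions.values()}
    roots = [a for a in p.activities if a not in has_incoming]
    succ: dict[str, list[str]] = {a: [] for a in p.activities}
    for t in p.transitions.values():
        succ[t.from_id].append(t.to_id)
    seen: set[str] = set()
    stack = list(roots)
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.add(n)
        stack.extend(succ[n])
    return seen
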