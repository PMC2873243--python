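# Methods

## The problem

Wet-lab protocols are normally written in natural language, which makes them
ambiguous ("incubate briefly", "shake gently"), hard to exchange, and
impossible to hand to an automated executor. labflow formalizes a protocol in
two coupled layers: an **ontology** that fixes what the laboratory's actions,
equipment and parameter types *are*, and a **workflow** that fixes in which
order, with which actual resources and by which executor the actions are
carried out. The two layers are saved as two linked standard-format files —
an XPDL 1.0 process definition and an OWL (RDF/XML) individuals file — so
that each can be consumed by its own tool ecosystem.

## The ontology stack

The stack has three levels, all held in one `DomainOntology`:

* **Core.** An `Action` class with three goal branches — `Separation`,
  `Transformation`, `Combination` — classifying what an experimental action
  does to material, and an `Equipment` class with `ActiveEntity` (performs
  actions: pipette, thermoblock) and `PassiveEntity` (acted upon: tube, swab)
  branches. Goals and agencies are inherited down the subclass chain unless
  a class declares its own; `goal_category` / `agency_category` resolve the
  nearest declared ancestor value. A class with no goal ancestor is flagged
  as a warning, not an error — classification is encouraged, not required.

* **Parameter layer.** Each *action template* (an OWL individual of an action
  class, e.g. `add_reagent_to_container`) carries ordered parameter lists
  with directions IN, OUT and IN_OUT, typed by the `Datatype` class: the
  union of `Equipment` and unit-bearing scalar properties
  (`owl:DatatypeProperty`, e.g. `volumeQuantity_ul`). This restructuring is
  what lines the ontology up with XPDL's IN/OUT/INOUT parameter-passing
  model: a template reads exactly like a function signature, and one template
  serves every protocol step performing that operation.

* **DSO.** The laboratory's own action classes, equipment classes, scalar
  properties, templates and individuals, attached under the core.

Two representation choices deserve a note. OWL property values are
unordered, so parameter order is carried by an explicit integer
`parameterPosition` annotation; conformance checking requires positions to
be consecutive from 0, which makes Application signatures deterministic.
Scalar units follow the `<name>_<unit>` suffix convention; the unit is
stored as a separate field (explicit `unit` annotation wins over the parsed
suffix at load) so tests can check units without string surgery. Unit
matching is **exact string equality** — no conversion table, because a
silent ml↔ul conversion is precisely the kind of hidden interpretation the
formalization exists to eliminate.

## Ontology → XPDL transformation

`translate_ontology` refuses non-conformant input, then:

* declares **every** equipment class and scalar property as an XPDL
  `TypeDeclaration` whose `ExternalReference` names the OWL file and the
  concept's local name — the ontology concept is referenced, never copied,
  and unreferenced datatypes are still declared (completeness over
  minimality);
* maps templates bijectively onto `Application` declarations, preserving
  parameter names, order, and directions (IN→IN, OUT→OUT, IN_OUT→INOUT).

Identifiers are sanitized local names; collisions get numeric suffixes in
lexicographic order of the original names, so the translation is a pure
function of the ontology.

## Protocols and typechecking

A protocol holds typed variables (equipment variables bound to ontology
individuals, scalar variables to literals with units), activities that
invoke Applications with actual-parameter bindings, transitions (conditions
are opaque strings; a conditional back-edge is a legal loop), and executors
(human / machine / software). The start marker is implicit: it feeds every
activity with no incoming transition.

`typecheck` is total — findings, never exceptions — with a fixed
code→severity table. Equipment compatibility is subclass subsumption
(`subclass_of`, reflexive transitive closure over the explicit parent
chain), chosen over exact-class matching because ontological subtyping means
substitutability: a `LysisBuffer` individual satisfies a `Reagent` slot.
Scalar compatibility is property identity plus exact unit match. IN/INOUT
parameters must be bound; OUT parameters must be bound to variables, not
literals; binding names must be a subset of the formal signature;
unreachable activities are errors. Unused variables and unclassified goals
are warnings and never block serialization (a CLI flag can force writing
despite errors).

`execution_order` is Kahn's algorithm with a lexicographic tie-break, run
first over all transitions and, when loops make that cyclic, over the
unconditional subgraph only; an unconditional cycle is an error. The
deterministic order also drives the left-to-right grid of graphical
coordinates embedded in the XPDL.

## Serialization

`write_package` emits `<name>.xpdl` and `<name>-individuals.owl`. The XPDL
uses the XPDL 1.0 namespace with the Tool/Application invocation style;
inline literal actuals are normalized into auto-named `DataField`s tagged
`InlineLiteral` so the calling convention stays uniform, and the reader
folds them back into literals. The individuals file types every equipment
individual by its DSO class and `owl:imports` the DSO by IRI; the DSO file
itself is referenced (relative path in every `ExternalReference`), never
rewritten. Output is canonical — fixed header values, sorted element
ordering, triples inserted in sorted order — so write→read→write reaches a
byte-identical fixpoint, which is what makes the interchange files
diff-able and version-controllable.

Emitted XPDL is validated against a vendored schema
(`schemas/xpdl_1_0_subset_synthetic.xsd`), a hand-written subset
reconstruction of XPDL 1.0 covering exactly the constructs the serializer
emits; it is not the official WfMC artifact. `read_package` validates,
re-links against an existing DSO (it never creates ontology classes), and
raises `LinkageError` on a dangling `ExternalReference` xref or a bound
individual missing from the individuals file.

## The worked example

`build_paternity_example` encodes the first three steps of a buccal-swab
paternity-test DNA-extraction protocol: cut the swab head into a 1.5 ml
Eppendorf tube (two activity blocks — one textual step may need several),
add lysis buffer with a pipette, incubate 30 minutes on a thermoblock. The
step table records per step the extracted verbs (`Cut`, `Add`, `Incubate`),
objects (`SwabHead`, `Eppendorf`, `Thermoblock`) and scalar values
(1.5 ml, 30 min). The `Add` class carries two templates
(`add_labware_to_container`, `add_reagent_to_container`), so translation
yields exactly two Applications from it. Conventions the step text does not
fix: the 1.5 ml is attached to the tube-capacity parameter of step 1, and
step 2's lysis-buffer volume (1500 ul, `LYSIS_BUFFER_VOLUME_UL`) is a
fixture constant so the protocol typechecks with all inputs bound — it is
deliberately excluded from the extracted-scalar table.

## The synthetic generator

`generate_random_package(seed, sizes, defect)` builds a conformant random
DSO (defaults: 5 action classes, 8 equipment classes, 4 scalar properties,
6 templates, 8 individuals — the scale of a small working DSO) and a
typecheck-clean protocol (6 activities on a random connected DAG), all from
one `random.Random(seed)`, so identical arguments reproduce identical
artifacts. Template `tmpl00` always has a fixed (equipment-IN, scalar-IN,
scalar-OUT) signature to give every mutation a deterministic anchor.
The defect harness injects exactly one violation — ontology-level
(`PARAM_TYPE_NOT_DATATYPE`, `UNRESOLVED_REFERENCE`, `DUPLICATE_POSITION`,
`NAME_COLLISION`, `PARENT_CYCLE`) or protocol-level (`TYPE_MISMATCH`,
`UNBOUND_INPUT`, `ARITY_MISMATCH`, `OUT_PARAM_LITERAL`, `MISSING_UNIT`,
`UNKNOWN_APPLICATION`, `UNREACHABLE_ACTIVITY`) — and records it in the
manifest, which serves as ground truth: the validators are scored on
reporting exactly the injected code and nothing else. Cross-file defects
(`corrupt_package_linkage`) are applied to written files.

What the generator does **not** emulate: real protocols have meaningful
names, uneven hierarchy depth, conditional branching with semantic
conditions, and multi-defect documents. Passing the mutation suites shows
the checkers are sound and complete for single defects from this catalogue
on this distribution of structures; it does not show anything about
recovering from several interacting defects, nor about ontologies that use
OWL constructs outside the scaffold (restrictions, imports beyond the
two-file chain, description-logic reasoning — all out of scope).

## Problem sizes and numerical choices

The property suites use 200 random DSOs for the mapping bijection, 100
packages for round-trip fixpoints, ≥100 single-defect mutations, and 1,000
random hierarchies/DAGs for the subsumption and topological-sort oracles —
sizes at which the whole suite and the acceptance script each finish in a
few seconds while exercising hierarchy depths and arities well beyond the
worked example. There are no floating-point tolerances anywhere: every
comparison in the system (units, names, positions, bytes) is exact, which
is the point of the formalization.

## Known limitations

* No execution/enactment: executors are declarations, not schedulers.
* No pre/post-condition reasoning over world state.
* No unit conversion, deliberately.
* The XPDL reader accepts the schema-valid subset this package writes, not
  arbitrary third-party XPDL.
* The core action/equipment vocabulary is minimal; real deployments are
  expected to grow their DSO, not the core.
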