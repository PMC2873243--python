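# labflow

Formal laboratory protocols as ontology-grounded XPDL workflows.

Natural-language lab protocols ("add lysis buffer", "incubate briefly") are
ambiguous, hard to exchange and impossible to automate. labflow is for
groups who want their bench protocols machine-checkable: it models the
laboratory's vocabulary as an ontology — actions classified by goal
(separation / transformation / combination), equipment split into active and
passive entities, unit-bearing scalar parameter types — and each protocol as
a typed workflow over that vocabulary. A protocol is saved as two linked
standard-format files: an **XPDL 1.0** process definition and an **OWL**
(RDF/XML) individuals file that imports the domain ontology.

The core mechanism is a model-to-model transformation. Each reusable
*action template* — an ontology individual with an ordered parameter
signature such as

```
add_reagent_to_container(IN pipette: Pipette,
                         IN reagent: Reagent,
                         IN volume: volumeQuantity_ul)
```

— becomes an XPDL `Application` with IN/OUT/INOUT formal parameters, and
every member of the `Datatype` union (equipment classes ∪ scalar
properties) becomes an XPDL `TypeDeclaration` whose `ExternalReference`
points back at the ontology concept. Workflow activities invoke the
Applications with actual parameters (variables bound to ontology
individuals, or scalar literals with units), and a static typechecker
enforces the ontology's constraints: subclass subsumption for equipment,
exact property-and-unit identity for scalars, every input bound, no
literals on OUT parameters, no unreachable activities.

## Worked example

The packaged example formalizes the first three steps of a buccal-swab
paternity-test DNA extraction:

```python
from labflow import translate_ontology, typecheck, write_package
from labflow.fixtures import build_paternity_example

ont, protocol = build_paternity_example()
tu = translate_ontology(ont)

add_apps = [a for a in tu.applications.values()
            if ont.templates[a.source_template].action_class == "Add"]
print(len(tu.applications), "applications,", len(add_apps), "from Add")
print("typecheck errors:", len([d for d in typecheck(protocol, ont, tu)
                                if d.is_error]))
```

prints

```
4 applications, 2 from Add
typecheck errors: 0
```

Four templates yield four Applications; the `Add` action class contributes
two of them (`add_labware_to_container`, `add_reagent_to_container`),
because placing the swab head in the tube and pipetting the buffer are
different operations sharing one action concept. Zero typecheck errors
means every activity's actual parameters satisfy the ontology: `myPipette`
is an individual of `Pipette`, `myLysisBuffer` of `LysisBuffer` (a
`Reagent` subclass — accepted by subsumption), and the scalar actuals carry
the exact units of their properties (1.5 ml tube capacity, 30 min
incubation).

The same package is available from the shell:

```sh
labflow demo --out out/            # dso.owl, paternity_test.xpdl,
                                   # paternity_test-individuals.owl, steps.txt
labflow validate --dso out/dso.owl --xpdl out/paternity_test.xpdl \
                 --owl out/paternity_test-individuals.owl
labflow translate --dso out/dso.owl --out out/tu.xpdl
```

`validate` exits 0 on a clean package, 1 on typecheck errors (JSON-line
diagnostics on stderr), 2 on I/O, schema or linkage failures. All outputs
are canonical: rerunning any command produces byte-identical files.

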