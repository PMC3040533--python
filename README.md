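# owlflow

Semantic annotation services, OWL-driven workflow planning, and SPARQL
query answering over a transient materialized RDF graph — with a worked
clinical example: finding kidney-transplant patients whose creatinine
trend marks them as *Likely Rejecters*.

## The problem

A SPARQL query may ask for data that does not exist yet in any database —
it has to be *computed*: a regression fitted, a latest value looked up, a
class membership derived.  This package implements, as one self-contained
library, the two pieces that make such queries answerable:

1. **The annotation-service contract.**  A service is described by two OWL
   classes — what it consumes and what it returns — over *same-URI*
   individuals: the service only adds RDF statements about the
   individuals it is given (plus nodes it mints and links to them).  What
   a service does is therefore derivable by comparing its input and
   output classes: the properties restricted in the output but not the
   input are its *attached predicates*, and a registry indexes services by
   them (and by class compatibility) for automatic discovery.

2. **The query engine.**  A SELECT query is deconstructed into triple
   patterns.  Patterns whose predicate is attached by a service become
   service invocations; `rdf:type` patterns naming a *defined* class are
   read as an **abstract workflow**: the class definition's requirements
   are recursively concretized into data lookups, service calls, and
   reasoning steps.  The resulting DAG executes over a transient graph —
   service outputs merged as they arrive, entailed types materialized by a
   forward-chaining reasoner for a positive OWL fragment (intersections,
   existential restrictions, value restrictions, numeric facets) — and the
   original query is finally evaluated over the materialized graph with
   plain SPARQL.  Every added triple is attributed to the service or
   reasoning round that produced it (full provenance).

The demo domain defines the cascade

    LikelyRejecter  ≡ Patient ⊓ ∃hasCreatinineCollection.ElevatedLevels
    ElevatedLevels  ≡ MeasurementCollection ⊓ ∃hasRegressionModel.IncreasingModel
    IncreasingModel ≡ LinearRegressionModel ⊓ ∃slope.(xsd:decimal > 0)

with three services (OLS regression over X-Y coordinate data, latest
creatinine, latest BUN) and a synthetic-cohort generator with emitted
ground truth.  The definition is deliberately a *hypothesis* — one
clinical perspective, encoded so a machine can find the individuals that
fit it.

## Worked example

```python
from owlflow import Registry, answer, demo_ontology, demo_services
from owlflow.synthetic_data import CohortSpec, generate_cohort

ont = demo_ontology()
reg = Registry(ontology=ont)
for s in demo_services():
    reg.register(s)

graph, truth = generate_cohort(
    CohortSpec(n_patients=10, fraction_rejecter=0.4, noise_sd=0.0, seed=1))

QUERY = """PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
PREFIX patients: <http://sadiframework.org/ontologies/patients.owl#>
PREFIX pred: <http://sadiframework.org/ontologies/predicates.owl#>
SELECT ?patient ?bun ?creat
FROM <http://sadiframework.org/ontologies/patients.rdf>
WHERE {
?patient rdf:type patients:LikelyRejecter.
?patient pred:latestBUN ?bun.
?patient pred:latestCreatinine ?creat.
}
"""

bindings, trace = answer(QUERY, graph, reg, ont)
print(bindings.to_csv())
```

prints

```
patient,bun,creat
http://owlflow.example.org/cohort/patient003,12.737934,2.4
http://owlflow.example.org/cohort/patient002,12.478599,2.4
http://owlflow.example.org/cohort/patient001,12.305638,2.4
http://owlflow.example.org/cohort/patient000,14.570628,2.4
```

The raw cohort contains no regression models and no latest values — only
measurement time-courses.  The engine discovered the regression service
(a time-course is declared a specialized kind of X-Y coordinate data),
fitted all series, classified the four patients whose creatinine slope is
strictly positive (2.4 mg/dL = 1.0 + 0.05/day × 28 days is each
rejecter's final, and here latest, value), and then invoked the
latest-value services for exactly those patients.  `trace` records which
step added each of the 174 new triples.

The `examples/` directory holds one short script per capability
(generation, annotation+classification, discovery, planning+answering);
the `owlflow` CLI (`generate`, `services`, `plan`, `query`, `explain`)
wraps the same functions for shell use.

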