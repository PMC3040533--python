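# Methods

This note records the models, conventions, and numerical choices behind
owlflow, and what the synthetic experiments do and do not demonstrate.

## Data model

RDF graphs are immutable sets of triples; merging is set union, which is
commutative, associative, and idempotent, so service outputs can be folded
into the working graph in any order.  Two restrictions are imposed on
instance data:

* **No blank-node subjects.**  The annotation-service contract states that
  input and output individuals share one URI; that promise is unverifiable
  for unnamed nodes, so instance data must name its individuals.  (OWL
  ontology documents, whose list structure legitimately uses blank nodes,
  are parsed separately and are exempt.)
* **Numeric literals compare by value.**  Every xsd numeric datatype is
  promoted to arbitrary-precision decimal before comparison, so
  `"1.0"^^xsd:decimal` and `"1"^^xsd:integer` denote the same node
  regardless of which serializer produced them.  Numeric literals must be
  finite; dateTimes must parse.

Turtle is the primary on-disk dialect; RDF/XML is accepted on input.  The
Turtle writer emits one sorted statement per line, so a graph always
serializes to identical bytes — fixtures are reproducible byte-for-byte.
SPARQL parsing and evaluation are delegated to rdflib.  A `FROM` clause is
honored by resolving it to the local graph being queried (the caller
decides which document the name denotes); nothing is ever dereferenced
over the network.

## The OWL fragment and the reasoner

Supported class expressions: named classes, intersections, existential
property restrictions (`someValuesFrom`), value restrictions (`hasValue`),
and numeric datatype ranges with the four xsd bound facets.  Everything in
this fragment is positive-existential, hence **monotone**: adding triples
can only add entailed memberships.  Monotonicity is what makes the
architecture sound — services and the reasoner can interleave freely.

`allValuesFrom`, cardinalities, unions, complements, and nominals are
rejected loudly at parse time.  This is deliberate, not a shortcut:
positive membership entailment for those constructs requires closed-world
assumptions a materializing engine cannot honestly make.  TBox
classification (class–class subsumption beyond asserted axioms) and
consistency checking are out of scope.

The built-in classifier materializes `rdf:type` assertions to fixpoint:
per individual, asserted types are closed upward under `rdfs:subClassOf`,
and membership in each defined class is decided by checking its
decomposed requirements (type requirements through the hierarchy and
definitions; property requirements through the `rdfs:subPropertyOf`
closure with recursive filler checks).  Definitions may cascade (a model
classified *increasing* makes a collection *elevated* makes a patient a
*rejecter*); the pass iterates until nothing new is derived, with a bound
of 10 iterations (exceeding it indicates a definition cycle, which is also
rejected statically).  Any external classifier with the same
`classify_all(graph, ontology) -> graph` contract can be substituted.

Numeric-range checks treat a non-numeric literal as a non-member with a
logged warning rather than an error: open-world data is messy, and one bad
literal should not abort the classification of a cohort.

## Services, registry, discovery

A service's *attached predicates* are the properties restricted in its
output class but not in its input class (both decomposed at top level).
Invocation enforces the input class per subject — violators are skipped
with a warning, and a per-subject implementation failure is recorded
without affecting the rest of the batch (batch-annotation semantics).
Contract validation checks (a) that every added triple's subject is an
input subject or a node reachable from one through the added triples
(services may mint, e.g., a regression-model node, provided it is rooted
at an input), and (b) that every subject the service reports success for
satisfies the output class after merge.

The registry indexes each attached predicate under itself and its declared
superproperties, so discovery by a more general predicate succeeds —
agreement on predicates, not classes, is the interoperability surface.
Class-compatibility matching (`find_consuming`) uses requirement coverage
under the subclass/subproperty closures and definition expansion: a sound,
decidable approximation of subsumption that stays inside the fragment.
Numeric-range fillers are matched by bound inclusion.  The exported
registry graph publishes the superproperty-closed attached predicates, so
plain SPARQL over it reproduces the in-memory index.

Service descriptions use a minimal self-defined vocabulary
(`.../ns/service-description/v1#`: inputClass, outputClass,
attachesPredicate, name), versioned by IRI.  Services are in-process
callables rebound by IRI on registry import; no HTTP binding is required
by any test.

## Planning

Coverage resolution per decomposed requirement, chosen where the design
was genuinely open:

* a **type membership** always resolves to the reasoner (asserted types
  are merely the data the reasoner reads);
* a **property restriction with a numeric-range or value filler** resolves
  to the reasoner — a facet check is pure logic over whatever data ends up
  present;
* a **property restriction with a class filler** resolves to `data` if any
  instance already carries the property (subproperty closure), else to
  *every* registered service attaching it (union is monotone and needs no
  ranking model), else stays `UNRESOLVED` — surfaced in the coverage
  table, never a silent empty answer.

Only the basic graph pattern drives planning; FILTER and other features
apply at final evaluation.  Property paths in a planning position are
rejected by name.  Patterns with unbound predicates resolve in-data, since
service mapping requires a known predicate.

Query-level service steps whose subject variable is also constrained by a
defined-class type pattern are scoped to that class and scheduled *after*
the classification step, so e.g. latest-value lookups run only for the
patients the classification selected.  Service-chain edges (one service's
attached property feeding another's input class) order service steps among
themselves.  Linearization is topological with ties broken by step label,
so planning is fully deterministic.

Services are invoked only for subjects still lacking the produced
predicate.  Under merge semantics this is purely an optimization — and it
is what makes re-execution on a final graph a no-op.

## Execution

Steps run in linearized order over a transient working graph; each service
delta is merged immediately.  After a pass that added triples the query is
re-planned against the enriched graph and executed again (a service output
may enable another service's input), up to 3 rounds by default — bounded
re-planning approximates a fixpoint without risking non-termination.  The
demo quiesces in two productive rounds (annotations+classification, then
the derived latest-value output classes).  A round that adds nothing ends
execution.  Per-step failures and unresolved requirements degrade
gracefully: recorded in the trace, skipped, never fatal.

The trace stores, per step, exactly the triples that were new when the
step ran; the deltas are therefore pairwise disjoint and partition the
added triples, giving exact per-triple provenance, and re-merging them
into the initial graph reproduces the final graph.

## The clinical demo

"Increasing" is read strictly: slope > 0, encoded as a `minExclusive 0`
facet on the slope of the fitted model.  A flat series is not increasing;
the boundary is exact because slope literals are compared as decimals.

The regression is plain unweighted OLS — slope = Σ(x−x̄)(y−ȳ)/Σ(x−x̄)²,
intercept = ȳ − slope·x̄ — requiring ≥ 2 distinct x values (`NotFittable`
below that; the service then skips that individual).  Model-node IRIs are
deterministic hash suffixes of the collection IRI, so re-runs mint the
same node.  "Latest" is the value at the maximum time offset, ties broken
by lexicographically greatest measurement IRI — an explicit, deterministic
convention.  The time axis is days since the patient's first measurement,
as decimal, keeping slopes (units/day) comparable across patients.

The Likely Rejecter definition itself is a hypothesis, not clinical
truth — clinically, creatinine need not be rising to be dangerously
elevated.  Threshold-based alternatives are an extension point, not
implemented.

## Synthetic cohorts

The generator emulates a transplant-clinic extract: per patient, weekly
creatinine and BUN series over five visits by default, creatinine base
1.0 mg/dL, rejecters trending +0.05 mg/dL/day, non-rejecters −0.02, BUN
base 15 mg/dL with a per-patient uniform slope in ±0.1, Gaussian noise
(default sd 0.05) and a 0.01 positivity floor.  Each patient draws from a
dedicated `(seed, index)` random stream, so enlarging a cohort never
shifts earlier patients.  Values are rounded to 6 decimals before both
serialization and ground-truth computation, so the oracle sees exactly the
bytes the graph holds.

Ground truth is defined by the *realized* data: the oracle label is the
sign of an independent OLS fit (numpy least squares, not the package's own
routine) on the noisy series.  This removes flakiness — borderline noisy
patients are labelled by what their data actually shows, which is what the
engine must reproduce.  The intended (generating-regime) label coincides
with the oracle label whenever the generating slope dominates the
noise-induced slope standard error; with the default margins this always
holds in the noiseless setting and essentially always at sd 0.05.

What passing these tests shows: the full discovery→planning→execution→
classification pipeline reproduces an independent analysis of the same
data, deterministically.  What it does not show: anything about real
clinical data — the generator has no missing values, no irregular
sampling, no pharmacokinetics, and no correlation between analytes.

## Problem sizes and tolerances

The test suite exercises: 100 random graph/expression pairs (≤ 20
individuals, expression depth ≤ 3) against a set-based model-checking
oracle; 20 noisy 50-patient cohorts against a full-materialization oracle;
≥ 50 fuzzed service invocations; 1000 random OLS fits at 1e-9 relative
tolerance against numpy.  These sizes keep the whole suite in the
low minutes on one CPU while covering every cascade the design admits;
`scripts/acceptance.py` re-runs the same studies from a single seed.
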