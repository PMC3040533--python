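"""The typed annotation-service contract.

A service is described by two OWL classes: what it consumes (input class)
and what it returns (output class).  The framework's central rule is the
**same-URI contract**: a service annotates the individuals it is given —
the URI of each input individual and of the corresponding output individual
is the same, so the service's entire effect is a set of new triples rooted
at its input subjects.  Consequently *what a service does* is derivable by
comparing the two classes: the properties restricted in the output class
but not in the input class are the service's attached predicates.

A service is also permitted to describe nodes it mints itself, provided
those nodes are reachable from an input subject through the triples added
in the same invocation (e.g. a regression service minting a model node and
attaching slope/intercept to it).

Invocation is batch-tolerant: a subject that does not satisfy the input
class, or for which the implementation fails, is skipped with a warning and
recorded — one bad individual never aborts a cohort.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, FrozenSet, Iterable, List, Optional, Set, Union

from .rdf_core import Graph, IRI, Literal, RDF_TYPE, Triple, graph_of
from .ontology_core import (
    ClassExpression,
    NamedClass,
    Ontology,
    PropertyReq,
    decompose,
    entails_membership,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ServiceDescription",
    "InvocationRecord",
    "ValidationReport",
    "SVC",
    "attached_properties",
    "invoke",
    "validate_contract",
    "describe",
    "interpret_description",
]

#: Minimal self-defined service-description vocabulary (versioned by IRI).
SVC = "http://owlflow.example.org/ns/service-description/v1#"
SVC_SERVICE = IRI(SVC + "Service")
SVC_NAME = IRI(SVC + "name")
SVC_INPUT_CLASS = IRI(SVC + "inputClass")
SVC_OUTPUT_CLASS = IRI(SVC + "outputClass")
SVC_ATTACHES = IRI(SVC + "attachesPredicate")

ClassRef = Union[IRI, ClassExpression]

#: invocation contract: (working graph, subject set) -> graph of added triples
Implementation = Callable[[Graph, Set[IRI]], Graph]


@dataclass(frozen=True)
class ServiceDescription:
    """Identity, input/output classes, and invocation contract of a service."""

    iri: IRI
    name: str
    input_class: ClassRef
    output_class: ClassRef
    implementation: Optional[Implementation] = None

    def same_interface(self, other: "ServiceDescription") -> bool:
        """Equality of the published description (the callable is not part
        of the service's identity)."""
        return (
            self.iri == other.iri
            and self.name == other.name
            and self.input_class == other.input_class
            and self.output_class == other.output_class
        )


@dataclass(frozen=True)
class InvocationRecord:
    """Provenance of one service invocation."""

    service: IRI
    input_subjects: FrozenSet[IRI]
    succeeded: FrozenSet[IRI]
    skipped: FrozenSet[IRI]
    errors: tuple  # ((subject IRI, message), ...)
    added_triples: Graph
    timestamp: str

    def __post_init__(self) -> None:
        assert self.succeeded <= self.input_subjects


@dataclass
class ValidationReport:
    """Outcome of checking an invocation against the service contract."""

    violations: List[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _class_iri(ref: ClassRef) -> Optional[IRI]:
    if isinstance(ref, IRI):
        return ref
    if isinstance(ref, NamedClass):
        return ref.iri
    return None


def attached_properties(s: ServiceDescription, ont: Ontology) -> Set[IRI]:
    """The service's advertised contribution: properties restricted in the
    output class but not in the input class (comparing decomposed
    requirements of the two)."""
    def props(ref: ClassRef) -> Set[IRI]:
        expr = ont.resolve(ref)
        return {r.property for r in decompose(expr) if isinstance(r, PropertyReq)}

    return props(s.output_class) - props(s.input_class)


def invoke(
    s: ServiceDescription,
    g: Graph,
    subjects: Iterable[IRI],
    ont: Ontology,
) -> InvocationRecord:
    """Invoke a service on a batch of subjects.

    Subjects not satisfying the input class are skipped with a warning;
    per-subject implementation failures are recorded without affecting the
    rest of the batch.  Returns only the *added* triples — the caller
    merges them into its working graph.
    """
    if s.implementation is None:
        raise ValueError(f"service {s.iri.value} has no bound implementation")
    input_expr = ont.resolve(s.input_class)
    accepted: List[IRI] = []
    skipped: Set[IRI] = set()
    for subj in sorted(set(subjects)):
        if entails_membership(g, subj, input_expr, ont):
            accepted.append(subj)
        else:
            skipped.add(subj)
            logger.warning(
                "service %s: subject %s does not satisfy the input class; skipped",
                s.iri.value,
                subj.value,
            )
    added = Graph()
    succeeded: Set[IRI] = set()
    errors: List[tuple] = []
    for subj in accepted:
        try:
            delta = s.implementation(g, {subj})
        except Exception as exc:
            errors.append((subj, str(exc)))
            logger.warning("service %s failed on %s: %s", s.iri.value, subj.value, exc)
            continue
        added = added.merge(delta)
        succeeded.add(subj)
    return InvocationRecord(
        service=s.iri,
        input_subjects=frozenset(accepted) | frozenset(skipped),
        succeeded=frozenset(succeeded),
        skipped=frozenset(skipped),
        errors=tuple(errors),
        added_triples=added,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
    )


def _reachable_subjects(added: Graph, roots: FrozenSet[IRI]) -> Set[IRI]:
    """Roots plus nodes reachable from them through the added triples
    (legitimate homes for triples about newly minted nodes)."""
    reach = set(roots)
    frontier = set(roots)
    while frontier:
        next_frontier = set()
        for t in added.triples:
            if t.subject in frontier and isinstance(t.object, IRI) and t.object not in reach:
                reach.add(t.object)
                next_frontier.add(t.object)
        frontier = next_frontier
    return reach


def validate_contract(
    s: ServiceDescription,
    g_in: Graph,
    record: InvocationRecord,
    ont: Ontology,
) -> ValidationReport:
    """Check an invocation against the same-URI contract.

    Violations: (a) an added triple whose subject is neither an input
    subject nor a node minted and reachable from one; (b) a subject the
    service claims to have succeeded on that does not satisfy the output
    class after merging the added triples.  Validation never throws.
    """
    report = ValidationReport()
    allowed = _reachable_subjects(record.added_triples, record.input_subjects)
    for t in record.added_triples.sorted_triples():
        if t.subject not in allowed:
            report.violations.append(
                f"same-URI violation: added triple subject {t.subject.value} is "
                "not an input subject nor reachable from one"
            )
    merged = g_in.merge(record.added_triples)
    output_expr = ont.resolve(s.output_class)
    for subj in sorted(record.succeeded):
        if not entails_membership(merged, subj, output_expr, ont):
            report.violations.append(
                f"output-class violation: subject {subj.value} does not satisfy "
                "the output class after merge"
            )
    return report


def describe(s: ServiceDescription, ont: Ontology) -> Graph:
    """The service's published RDF description (name, I/O classes, attached
    predicates).  Requires the I/O classes to be named, so the description
    round-trips through the registry export."""
    in_iri = _class_iri(s.input_class)
    out_iri = _class_iri(s.output_class)
    if in_iri is None or out_iri is None:
        raise ValueError(
            f"service {s.iri.value}: only named input/output classes can be published"
        )
    triples = [
        Triple(s.iri, RDF_TYPE, SVC_SERVICE),
        Triple(s.iri, SVC_NAME, Literal(s.name)),
        Triple(s.iri, SVC_INPUT_CLASS, in_iri),
        Triple(s.iri, SVC_OUTPUT_CLASS, out_iri),
    ]
    # published under the declared superproperties too, so plain SPARQL over
    # the description graph reproduces subsumption-aware predicate discovery
    closed = set()
    for p in attached_properties(s, ont):
        closed |= ont.superproperties(p)
    for p in sorted(closed):
        triples.append(Triple(s.iri, SVC_ATTACHES, p))
    return graph_of(triples)


def interpret_description(
    g: Graph,
    service_iri: IRI,
    implementation: Optional[Implementation] = None,
) -> ServiceDescription:
    """Rebuild a ServiceDescription from its RDF description; the
    implementation callable, if any, is rebound by IRI by the caller."""
    name = g.value(service_iri, SVC_NAME)
    in_cls = g.value(service_iri, SVC_INPUT_CLASS)
    out_cls = g.value(service_iri, SVC_OUTPUT_CLASS)
    if not isinstance(in_cls, IRI) or not isinstance(out_cls, IRI):
        raise ValueError(f"incomplete service description for {service_iri.value}")
    return ServiceDescription(
        iri=service_iri,
        name=name.lexical_form if isinstance(name, Literal) else "",
        input_class=in_cls,
        output_class=out_cls,
        implementation=implementation,
    )
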