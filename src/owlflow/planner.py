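"""Turn a SPARQL query plus an ontology into an ordered workflow.

A SELECT query is deconstructed into its basic-graph-pattern triples.  Each
pattern resolves one of three ways:

* ``in-data`` — the pattern can be answered from triples already present;
* ``service`` — the pattern's predicate is attached by one or more
  registered annotation services, which will be invoked to materialize it;
* ``class-plan`` — the pattern is ``rdf:type`` with a *defined* class as
  object: the class definition is read as an abstract workflow, its
  requirements recursively concretized (data lookup, service call, or
  reasoning step) and a classification pass appended.

The resulting workflow is a DAG: services producing a property precede the
reasoning step that consumes it, and query-level predicate services whose
subjects are narrowed by a classification (e.g. latest-value lookups for
the patients a class-plan selects) run after that classification.  The
linearization is deterministic — topological order with ties broken by step
label — so identical inputs always yield identical plans.

Anything the plan cannot cover is surfaced as an ``UNRESOLVED`` coverage
entry rather than silently producing empty answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple, Union

from rdflib import URIRef, Variable
from rdflib.plugins.sparql.algebra import translateQuery
from rdflib.plugins.sparql.parser import parseQuery

from .rdf_core import (
    Graph,
    GraphError,
    IRI,
    Literal,
    QueryError,
    RDF_TYPE,
    Term,
    _from_rdflib_term,
)
from .ontology_core import (
    ClassExpression,
    HasValue,
    IntersectionOf,
    MembershipReq,
    NamedClass,
    NumericRange,
    Ontology,
    OWL_THING,
    PropertyReq,
    Requirement,
    SomeValuesFrom,
    decompose,
)
from .registry import Registry

__all__ = [
    "Var",
    "TriplePattern",
    "ServiceStep",
    "ReasonStep",
    "Workflow",
    "PatternResolution",
    "QueryPlan",
    "CoverageEntry",
    "PlanError",
    "plan_for_class",
    "plan_for_query",
    "coverage_report",
    "extract_patterns",
]


class PlanError(GraphError):
    pass


@dataclass(frozen=True)
class Var:
    name: str

    def __repr__(self) -> str:
        return f"?{self.name}"


PatternTerm = Union[Var, IRI, Literal]


@dataclass(frozen=True)
class TriplePattern:
    subject: PatternTerm
    predicate: PatternTerm
    object: PatternTerm

    def __repr__(self) -> str:
        def fmt(t):
            return repr(t) if isinstance(t, Var) else (
                f"<{t.value}>" if isinstance(t, IRI) else f'"{t.lexical_form}"'
            )

        return f"{fmt(self.subject)} {fmt(self.predicate)} {fmt(self.object)}"


# ---------------------------------------------------------------------------
# workflow steps
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ServiceStep:
    """Invoke one service to attach one predicate.

    ``selector`` narrows the target subjects (a class the subjects must be
    entailed members of — e.g. the defined class that a preceding
    classification assigns); ``fixed_subjects`` pins them outright.  With
    neither, targets are the individuals satisfying the service's input
    class.  Subjects already carrying the produced predicate are skipped.
    """

    service: IRI
    produces: IRI
    selector: Optional[IRI] = None
    fixed_subjects: FrozenSet[IRI] = frozenset()

    @property
    def label(self) -> str:
        return f"service {self.service.value} [{self.produces.value}]"


@dataclass(frozen=True)
class ReasonStep:
    """Run the classifier over the whole working graph."""

    @property
    def label(self) -> str:
        return "reason"


WorkflowStep = Union[ServiceStep, ReasonStep]

#: coverage resolutions
DATA, SERVICE, REASONER, UNRESOLVED = "data", "service", "reasoner", "UNRESOLVED"


@dataclass(frozen=True)
class CoverageEntry:
    requirement: Requirement
    resolution: str  # data | service | reasoner | UNRESOLVED
    services: Tuple[IRI, ...] = ()

    def render(self) -> str:
        req = self.requirement
        if isinstance(req, MembershipReq):
            what = f"membership in <{req.class_iri.value}>"
        else:
            what = f"property <{req.property.value}>"
        via = ""
        if self.services:
            via = " via " + ", ".join(s.value for s in self.services)
        return f"{what}: {self.resolution}{via}"


@dataclass
class Workflow:
    """A DAG of steps with precedence edges, plus the coverage table."""

    steps: List[WorkflowStep] = field(default_factory=list)
    edges: Set[Tuple[str, str]] = field(default_factory=set)
    coverage: List[CoverageEntry] = field(default_factory=list)

    def add_step(self, step: WorkflowStep) -> WorkflowStep:
        if all(s.label != step.label for s in self.steps):
            self.steps.append(step)
        return step

    def add_edge(self, before: WorkflowStep, after: WorkflowStep) -> None:
        if before.label != after.label:
            self.edges.add((before.label, after.label))

    def linearize(self) -> List[WorkflowStep]:
        """Deterministic topological order (ties by step label)."""
        by_label = {s.label: s for s in self.steps}
        indeg = {l: 0 for l in by_label}
        for a, b in self.edges:
            if a in indeg and b in indeg:
                indeg[b] += 1
        order: List[WorkflowStep] = []
        ready = sorted(l for l, d in indeg.items() if d == 0)
        while ready:
            label = ready.pop(0)
            order.append(by_label[label])
            for a, b in sorted(self.edges):
                if a == label and b in indeg:
                    indeg[b] -= 1
                    if indeg[b] == 0:
                        ready.append(b)
            ready.sort()
        if len(order) != len(self.steps):
            raise PlanError("workflow precedence edges contain a cycle")
        return order

    def unresolved(self) -> List[CoverageEntry]:
        return [c for c in self.coverage if c.resolution == UNRESOLVED]

    def merge_into(self, other: "Workflow") -> None:
        for s in self.steps:
            other.add_step(s)
        other.edges |= self.edges
        seen = {c.requirement for c in other.coverage}
        for c in self.coverage:
            if c.requirement not in seen:
                other.coverage.append(c)
                seen.add(c.requirement)


@dataclass(frozen=True)
class PatternResolution:
    pattern: TriplePattern
    resolution: str  # in-data | service | class-plan
    services: Tuple[IRI, ...] = ()
    class_iri: Optional[IRI] = None


@dataclass
class QueryPlan:
    query: str
    patterns: List[PatternResolution]
    workflow: Workflow


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _data_has_property(g: Graph, p: IRI, ont: Ontology) -> bool:
    preds = ont.subproperties(p)
    return any(t.predicate in preds for t in g.triples)


def _required_properties(ont: Ontology, expr: ClassExpression, seen: Set[IRI]) -> Set[IRI]:
    """All properties an input class requires, through nested fillers and
    class definitions — used to order chained services."""
    out: Set[IRI] = set()
    for req in decompose(expr):
        if isinstance(req, MembershipReq):
            defn = ont.class_definitions.get(req.class_iri)
            if defn is not None and req.class_iri not in seen:
                out |= _required_properties(ont, defn, seen | {req.class_iri})
        else:
            out.add(req.property)
            f = req.filler
            if isinstance(f, (NamedClass, IntersectionOf, SomeValuesFrom, HasValue)):
                out |= _required_properties(ont, f, seen)
    return out


def _chain_edges(wf: Workflow, r: Registry, ont: Ontology) -> None:
    """Add precedence between service steps when one's output feeds
    another's input class."""
    from .service_model import attached_properties

    svc_steps = [s for s in wf.steps if isinstance(s, ServiceStep)]
    for s1 in svc_steps:
        d1 = r.get(s1.service)
        if d1 is None:
            continue
        out_props = attached_properties(d1, ont)
        for s2 in svc_steps:
            if s1.label == s2.label:
                continue
            d2 = r.get(s2.service)
            if d2 is None:
                continue
            needs = _required_properties(ont, ont.resolve(d2.input_class), set())
            if out_props & needs:
                wf.add_edge(s1, s2)


# ---------------------------------------------------------------------------
# class planning
# ---------------------------------------------------------------------------


def plan_for_class(
    class_ref: Union[IRI, ClassExpression],
    r: Registry,
    ont: Ontology,
    g: Graph,
) -> Workflow:
    """Concretize a class definition into a workflow.

    Recursively walks the decomposed requirements of the class and of every
    defined class it references.  Type memberships and facet/value checks
    go to the reasoner; property restrictions resolve to the data when
    instances already carry the property, else to every registered service
    attaching it, else stay UNRESOLVED.  A final classification step closes
    the workflow, preceded by every service step.
    """
    wf = Workflow()
    reason = ReasonStep()
    seen_reqs: Set[Requirement] = set()
    visited_classes: Set[IRI] = set()

    def add_cov(entry: CoverageEntry) -> None:
        if entry.requirement not in seen_reqs:
            seen_reqs.add(entry.requirement)
            wf.coverage.append(entry)

    def visit(expr: ClassExpression) -> None:
        for req in decompose(expr):
            if isinstance(req, MembershipReq):
                add_cov(CoverageEntry(req, REASONER))
                defn = ont.class_definitions.get(req.class_iri)
                if defn is not None and req.class_iri not in visited_classes:
                    visited_classes.add(req.class_iri)
                    visit(defn)
            else:
                filler = req.filler
                if isinstance(filler, (NumericRange, IRI, Literal)):
                    # facet / value checks are pure logic
                    add_cov(CoverageEntry(req, REASONER))
                    continue
                if _data_has_property(g, req.property, ont):
                    add_cov(CoverageEntry(req, DATA))
                else:
                    matches = r.find_by_predicate(req.property)
                    if matches:
                        iris = tuple(s.iri for s in matches)
                        add_cov(CoverageEntry(req, SERVICE, iris))
                        for s in matches:
                            step = wf.add_step(ServiceStep(s.iri, req.property))
                            wf.add_edge(step, reason)
                    else:
                        add_cov(CoverageEntry(req, UNRESOLVED))
                visit(filler)

    start = ont.resolve(class_ref)
    if isinstance(class_ref, IRI):
        visited_classes.add(class_ref)
        add_cov(CoverageEntry(MembershipReq(class_ref), REASONER))
    visit(start)
    wf.add_step(reason)
    for s in wf.steps:
        if isinstance(s, ServiceStep):
            wf.add_edge(s, reason)
    _chain_edges(wf, r, ont)
    return wf


# ---------------------------------------------------------------------------
# query planning
# ---------------------------------------------------------------------------


def extract_patterns(query: str) -> List[TriplePattern]:
    """The basic-graph-pattern triples of a SELECT query, in document order.

    Solution modifiers, FILTER and such are ignored here (they apply at
    final evaluation); features the planner cannot inspect, like property
    paths, raise :class:`PlanError` naming the feature.
    """
    try:
        algebra = translateQuery(parseQuery(query)).algebra
    except Exception as exc:
        raise QueryError(f"malformed SPARQL query: {exc}") from exc

    triples: List[Tuple] = []

    def walk(node) -> None:
        if hasattr(node, "name") and getattr(node, "name", None) == "BGP":
            triples.extend(node.triples)
            return
        if hasattr(node, "keys"):
            for key in node:
                val = node[key]
                if hasattr(val, "keys"):
                    walk(val)
                elif isinstance(val, list):
                    for item in val:
                        if hasattr(item, "keys"):
                            walk(item)

    walk(algebra)

    def conv(term) -> PatternTerm:
        if isinstance(term, Variable):
            return Var(str(term))
        if isinstance(term, URIRef):
            return IRI(str(term))
        try:
            return _from_rdflib_term(term)
        except Exception:
            raise PlanError(
                f"unsupported term in planning position: {type(term).__name__}"
            )

    out = []
    for s, p, o in triples:
        if not isinstance(p, (Variable, URIRef)):
            raise PlanError(
                f"unsupported feature in predicate position: {type(p).__name__} "
                "(property paths are not plannable)"
            )
        out.append(TriplePattern(conv(s), conv(p), conv(o)))
    return out


def plan_for_query(q: str, r: Registry, ont: Ontology, g: Graph) -> QueryPlan:
    """Resolve every triple pattern of the query and merge the per-class
    workflows with the query-level service steps into one ordered plan."""
    patterns = extract_patterns(q)
    wf = Workflow()
    reason = ReasonStep()
    wf.add_step(reason)
    resolutions: List[PatternResolution] = []

    # variables classified by a class-plan (subject var -> defined class)
    classified_vars: Dict[Var, IRI] = {}
    for pat in patterns:
        if (
            pat.predicate == RDF_TYPE
            and isinstance(pat.object, IRI)
            and pat.object in ont.class_definitions
            and isinstance(pat.subject, Var)
        ):
            classified_vars[pat.subject] = pat.object

    for pat in patterns:
        if pat.predicate == RDF_TYPE and isinstance(pat.object, IRI):
            if pat.object in ont.class_definitions:
                sub_wf = plan_for_class(pat.object, r, ont, g)
                sub_wf.merge_into(wf)
                resolutions.append(
                    PatternResolution(pat, "class-plan", class_iri=pat.object)
                )
                continue
            resolutions.append(PatternResolution(pat, "in-data"))
            continue
        if isinstance(pat.predicate, Var):
            # service mapping needs a known predicate
            resolutions.append(PatternResolution(pat, "in-data"))
            continue
        p = pat.predicate
        if _data_has_property(g, p, ont):
            resolutions.append(PatternResolution(pat, "in-data"))
            continue
        matches = r.find_by_predicate(p)
        if not matches:
            resolutions.append(PatternResolution(pat, "in-data"))
            req = PropertyReq(p, NamedClass(OWL_THING))
            if req not in {c.requirement for c in wf.coverage}:
                wf.coverage.append(CoverageEntry(req, UNRESOLVED))
            continue
        iris = tuple(s.iri for s in matches)
        resolutions.append(PatternResolution(pat, "service", services=iris))
        selector: Optional[IRI] = None
        fixed: FrozenSet[IRI] = frozenset()
        if isinstance(pat.subject, Var):
            selector = classified_vars.get(pat.subject)
        elif isinstance(pat.subject, IRI):
            fixed = frozenset({pat.subject})
        for s in matches:
            step = wf.add_step(ServiceStep(s.iri, p, selector=selector, fixed_subjects=fixed))
            if selector is not None:
                # run after classification narrows the subjects
                wf.add_edge(reason, step)
            else:
                wf.add_edge(step, reason)
        req = PropertyReq(p, NamedClass(OWL_THING))
        if req not in {c.requirement for c in wf.coverage}:
            wf.coverage.append(CoverageEntry(req, SERVICE, iris))

    _chain_edges(wf, r, ont)
    return QueryPlan(query=q, patterns=resolutions, workflow=wf)


# ---------------------------------------------------------------------------
# coverage report
# ---------------------------------------------------------------------------


def coverage_report(plan: Union[QueryPlan, Workflow]) -> str:
    """Human-readable coverage table: every requirement and how the plan
    resolves it; UNRESOLVED entries name the predicate or class that no
    data or service supplies."""
    wf = plan.workflow if isinstance(plan, QueryPlan) else plan
    lines = ["coverage:"]
    for entry in wf.coverage:
        lines.append("  " + entry.render())
    unresolved = wf.unresolved()
    lines.append(f"unresolved requirements: {len(unresolved)}")
    return "\n".join(lines)


def plan_to_dict(plan: QueryPlan) -> dict:
    """Machine-readable plan export (stable schema, YAML/JSON friendly)."""
    wf = plan.workflow
    return {
        "query": plan.query,
        "patterns": [
            {
                "pattern": repr(p.pattern),
                "resolution": p.resolution,
                "services": [s.value for s in p.services],
                "class": p.class_iri.value if p.class_iri else None,
            }
            for p in plan.patterns
        ],
        "steps": [
            {"label": s.label}
            | (
                {
                    "service": s.service.value,
                    "produces": s.produces.value,
                    "selector": s.selector.value if s.selector else None,
                }
                if isinstance(s, ServiceStep)
                else {"kind": "reason"}
            )
            for s in wf.linearize()
        ],
        "coverage": [
            {
                "requirement": c.render().split(":")[0],
                "resolution": c.resolution,
                "services": [s.value for s in c.services],
            }
            for c in wf.coverage
        ],
    }
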