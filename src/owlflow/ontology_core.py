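"""Class-expression algebra and instance reasoning for a positive OWL fragment.

The supported fragment is deliberately small: named classes, intersections,
existential property restrictions (``someValuesFrom``), value restrictions
(``hasValue``) and numeric datatype ranges with xsd facets.  Everything in it
is positive-existential, which buys two properties the query engine depends
on:

* **monotonicity** — adding triples can only add entailed class
  memberships, never retract them, so annotation-service outputs can be
  merged into the working graph in any order;
* **decomposability** — every expression flattens into a conjunction of
  atomic *requirements* (type memberships and property restrictions), which
  is what lets a class definition be read as an abstract workflow.

Constructs outside the fragment (``allValuesFrom``, cardinalities, unions,
complements) are rejected loudly at parse time, never silently dropped:
positive membership entailment for them would require closed-world
assumptions that a graph-materializing engine cannot honestly make.

The built-in reasoner (:func:`classify_all`) materializes ``rdf:type``
assertions to fixpoint.  Any external classifier with the same contract can
be plugged in wherever a reasoner callable is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple, Union

import rdflib
from rdflib import BNode, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .rdf_core import (
    XSD,
    Graph,
    GraphError,
    IRI,
    Literal,
    RDF_TYPE,
    Term,
    Triple,
    _from_rdflib_term,
    _to_rdflib_term,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NamedClass",
    "IntersectionOf",
    "SomeValuesFrom",
    "HasValue",
    "NumericRange",
    "ClassExpression",
    "MembershipReq",
    "PropertyReq",
    "Requirement",
    "Ontology",
    "OWL_THING",
    "UnsupportedFragmentError",
    "CyclicDefinitionError",
    "FixpointError",
    "parse_class_expression",
    "load_ontology",
    "ontology_to_turtle",
    "decompose",
    "entails_membership",
    "classify_all",
]

OWL_THING = IRI(str(OWL.Thing))

FACET_NAMES = ("minInclusive", "maxInclusive", "minExclusive", "maxExclusive")


class UnsupportedFragmentError(GraphError):
    """An OWL construct outside the supported fragment was encountered."""


class CyclicDefinitionError(GraphError):
    """Class definitions refer to each other in a cycle."""


class FixpointError(GraphError):
    """Classification failed to reach a fixpoint within the iteration bound."""


# ---------------------------------------------------------------------------
# Class-expression algebra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NamedClass:
    iri: IRI


@dataclass(frozen=True)
class NumericRange:
    """A numeric datatype with optional xsd facet bounds.

    ``facets`` maps facet names (minInclusive, maxInclusive, minExclusive,
    maxExclusive) to Decimal bounds.  An empty facet set admits any finite
    number of the datatype.
    """

    datatype: IRI
    facet_items: Tuple[Tuple[str, Decimal], ...] = ()

    def __post_init__(self) -> None:
        for name, _ in self.facet_items:
            if name not in FACET_NAMES:
                raise GraphError(f"unknown facet {name!r}")
        f = self.facets
        lo = max((v for k, v in f.items() if k.startswith("min")), default=None)
        hi = min((v for k, v in f.items() if k.startswith("max")), default=None)
        if lo is not None and hi is not None and lo > hi:
            raise GraphError(f"inconsistent numeric facets: lower {lo} > upper {hi}")

    @property
    def facets(self) -> Dict[str, Decimal]:
        return dict(self.facet_items)

    @classmethod
    def of(cls, datatype: IRI, **facets) -> "NumericRange":
        items = tuple(
            (name, Decimal(str(facets[name]))) for name in FACET_NAMES if name in facets
        )
        return cls(datatype, items)

    def contains(self, value: Decimal) -> bool:
        f = self.facets
        if "minInclusive" in f and not value >= f["minInclusive"]:
            return False
        if "minExclusive" in f and not value > f["minExclusive"]:
            return False
        if "maxInclusive" in f and not value <= f["maxInclusive"]:
            return False
        if "maxExclusive" in f and not value < f["maxExclusive"]:
            return False
        return True


@dataclass(frozen=True)
class IntersectionOf:
    members: Tuple["ClassExpression", ...]

    def __post_init__(self) -> None:
        if not self.members:
            # empty conjunction is vacuously true: normalize to owl:Thing
            object.__setattr__(self, "members", (NamedClass(OWL_THING),))


@dataclass(frozen=True)
class SomeValuesFrom:
    property: IRI
    filler: Union["ClassExpression", NumericRange]


@dataclass(frozen=True)
class HasValue:
    property: IRI
    value: Term


ClassExpression = Union[NamedClass, IntersectionOf, SomeValuesFrom, HasValue]


# ---------------------------------------------------------------------------
# Requirements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MembershipReq:
    class_iri: IRI


@dataclass(frozen=True)
class PropertyReq:
    """A property restriction: the individual must have a ``property`` edge
    whose value satisfies ``filler`` (a class expression, a numeric range,
    or — for hasValue — a specific term)."""

    property: IRI
    filler: Union[ClassExpression, NumericRange, IRI, Literal]


Requirement = Union[MembershipReq, PropertyReq]


def decompose(expr: ClassExpression) -> List[Requirement]:
    """Flatten an expression into its conjunction of atomic requirements.

    Nested intersections are flattened; order follows document order, so
    decomposition is deterministic.  The conjunction of the returned
    requirements is logically equivalent to the input expression.
    """
    if isinstance(expr, NamedClass):
        return [MembershipReq(expr.iri)]
    if isinstance(expr, IntersectionOf):
        out: List[Requirement] = []
        for m in expr.members:
            out.extend(decompose(m))
        return out
    if isinstance(expr, SomeValuesFrom):
        return [PropertyReq(expr.property, expr.filler)]
    if isinstance(expr, HasValue):
        return [PropertyReq(expr.property, expr.value)]
    raise GraphError(f"cannot decompose {expr!r}")


def expression_properties(expr: ClassExpression) -> Set[IRI]:
    """The properties restricted at the top level of ``expr``."""
    return {r.property for r in decompose(expr) if isinstance(r, PropertyReq)}


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------


def _transitive_closure(pairs: Set[Tuple[IRI, IRI]]) -> Dict[IRI, Set[IRI]]:
    """Transitive closure by iterated relational join; sound on cycles
    (a node on a cycle ends up reachable from itself)."""
    closed: Dict[IRI, Set[IRI]] = {}
    for sub, sup in pairs:
        closed.setdefault(sub, set()).add(sup)
    changed = True
    while changed:
        changed = False
        for node, sups in closed.items():
            extra: Set[IRI] = set()
            for s in sups:
                extra |= closed.get(s, set())
            if not extra <= sups:
                sups |= extra
                changed = True
    return closed


@dataclass
class Ontology:
    """Equivalence definitions plus subclass/subproperty hierarchies.

    The hierarchies must be acyclic over named terms (the reflexive pairs
    C ⊑ C are tolerated and ignored).
    """

    class_definitions: Dict[IRI, ClassExpression] = field(default_factory=dict)
    subclass_axioms: Set[Tuple[IRI, IRI]] = field(default_factory=set)
    subproperty_axioms: Set[Tuple[IRI, IRI]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self._check_acyclic(self.subclass_axioms, "subclass")
        self._check_acyclic(self.subproperty_axioms, "subproperty")
        self._check_definition_cycles()
        # closures are queried hot during reasoning; precompute once
        # (ontologies are treated as immutable after construction)
        self._up_class = _transitive_closure(self.subclass_axioms)
        self._down_class = _transitive_closure({(b, a) for a, b in self.subclass_axioms})
        self._up_prop = _transitive_closure(self.subproperty_axioms)
        self._down_prop = _transitive_closure({(b, a) for a, b in self.subproperty_axioms})

    @staticmethod
    def _check_acyclic(pairs: Set[Tuple[IRI, IRI]], label: str) -> None:
        closure = _transitive_closure({(a, b) for a, b in pairs if a != b})
        for node, sups in closure.items():
            if node in sups:
                raise CyclicDefinitionError(f"cyclic {label} hierarchy at {node.value}")

    def _definition_refs(self, expr) -> Set[IRI]:
        if isinstance(expr, NamedClass):
            return {expr.iri} if expr.iri in self.class_definitions else set()
        if isinstance(expr, IntersectionOf):
            out: Set[IRI] = set()
            for m in expr.members:
                out |= self._definition_refs(m)
            return out
        if isinstance(expr, SomeValuesFrom) and not isinstance(expr.filler, NumericRange):
            return self._definition_refs(expr.filler)
        return set()

    def _check_definition_cycles(self) -> None:
        edges = {
            (c, ref)
            for c, expr in self.class_definitions.items()
            for ref in self._definition_refs(expr)
        }
        closure = _transitive_closure({(a, b) for a, b in edges if a != b})
        for c in self.class_definitions:
            if c in closure.get(c, set()) or (c, c) in edges:
                raise CyclicDefinitionError(f"class definition cycle at {c.value}")

    # -- hierarchy queries ---------------------------------------------------

    def superclasses(self, c: IRI) -> Set[IRI]:
        """Reflexive-transitive superclasses of a named class."""
        return {c} | self._up_class.get(c, set())

    def superproperties(self, p: IRI) -> Set[IRI]:
        return {p} | self._up_prop.get(p, set())

    def subproperties(self, p: IRI) -> Set[IRI]:
        return {p} | self._down_prop.get(p, set())

    def subclasses(self, c: IRI) -> Set[IRI]:
        return {c} | self._down_class.get(c, set())

    def definition(self, c: IRI) -> Optional[ClassExpression]:
        return self.class_definitions.get(c)

    def resolve(self, ref: Union[IRI, ClassExpression]) -> ClassExpression:
        """An IRI resolves to its definition if it has one, else NamedClass."""
        if isinstance(ref, IRI):
            return self.class_definitions.get(ref, NamedClass(ref))
        return ref

    def merged(self, other: "Ontology") -> "Ontology":
        defs = dict(self.class_definitions)
        defs.update(other.class_definitions)
        return Ontology(
            defs,
            set(self.subclass_axioms) | set(other.subclass_axioms),
            set(self.subproperty_axioms) | set(other.subproperty_axioms),
        )


EMPTY_ONTOLOGY = Ontology()


# ---------------------------------------------------------------------------
# OWL parsing (rdflib-level, because OWL list structure uses blank nodes)
# ---------------------------------------------------------------------------

_UNSUPPORTED = {
    OWL.allValuesFrom: "allValuesFrom",
    OWL.cardinality: "cardinality",
    OWL.minCardinality: "minCardinality",
    OWL.maxCardinality: "maxCardinality",
    OWL.qualifiedCardinality: "qualifiedCardinality",
    OWL.minQualifiedCardinality: "minQualifiedCardinality",
    OWL.maxQualifiedCardinality: "maxQualifiedCardinality",
    OWL.unionOf: "unionOf",
    OWL.complementOf: "complementOf",
    OWL.oneOf: "oneOf",
}

_XSD_NUMERIC_PREFIX = XSD


def _rdf_list(rg: rdflib.Graph, head) -> List:
    items = []
    node = head
    while node and node != RDF.nil:
        items.append(rg.value(node, RDF.first))
        node = rg.value(node, RDF.rest)
    return items


def _parse_numeric_range(rg: rdflib.Graph, node) -> NumericRange:
    if isinstance(node, URIRef):
        return NumericRange(IRI(str(node)))
    dt = rg.value(node, OWL.onDatatype)
    if dt is None:
        raise UnsupportedFragmentError("datatype restriction without owl:onDatatype")
    facets: List[Tuple[str, Decimal]] = []
    restrictions = rg.value(node, OWL.withRestrictions)
    if restrictions is not None:
        for facet_node in _rdf_list(rg, restrictions):
            for name in FACET_NAMES:
                val = rg.value(facet_node, URIRef(XSD + name))
                if val is not None:
                    facets.append((name, Decimal(str(val))))
    return NumericRange(IRI(str(dt)), tuple(facets))


def _is_datatype_node(rg: rdflib.Graph, node) -> bool:
    if isinstance(node, URIRef):
        return str(node).startswith(_XSD_NUMERIC_PREFIX)
    return (node, RDF.type, RDFS.Datatype) in rg or rg.value(node, OWL.onDatatype) is not None


def _parse_expr(rg: rdflib.Graph, node, depth: int = 0) -> ClassExpression:
    if depth > 50:
        raise CyclicDefinitionError("class expression nesting exceeds depth bound")
    if isinstance(node, URIRef):
        return NamedClass(IRI(str(node)))
    for pred, name in _UNSUPPORTED.items():
        if rg.value(node, pred) is not None:
            raise UnsupportedFragmentError(
                f"owl:{name} is outside the supported class-expression fragment"
            )
    inter = rg.value(node, OWL.intersectionOf)
    if inter is not None:
        members = tuple(_parse_expr(rg, m, depth + 1) for m in _rdf_list(rg, inter))
        return IntersectionOf(members)
    on_prop = rg.value(node, OWL.onProperty)
    if on_prop is not None:
        some = rg.value(node, OWL.someValuesFrom)
        if some is not None:
            if _is_datatype_node(rg, some):
                return SomeValuesFrom(IRI(str(on_prop)), _parse_numeric_range(rg, some))
            return SomeValuesFrom(IRI(str(on_prop)), _parse_expr(rg, some, depth + 1))
        has_val = rg.value(node, OWL.hasValue)
        if has_val is not None:
            return HasValue(IRI(str(on_prop)), _from_rdflib_term(has_val))
        raise UnsupportedFragmentError(
            "owl:Restriction with neither someValuesFrom nor hasValue"
        )
    raise UnsupportedFragmentError(f"unrecognized class-expression node {node!r}")


def _as_rdflib_graph(g: Union[Graph, rdflib.Graph]) -> rdflib.Graph:
    if isinstance(g, rdflib.Graph):
        return g
    from .rdf_core import to_rdflib

    return to_rdflib(g)


def parse_class_expression(
    ontology_graph: Union[Graph, rdflib.Graph], class_iri: IRI
) -> ClassExpression:
    """The algebraic form of a class: its equivalence definition if present,
    otherwise the primitive ``NamedClass``.

    Raises :class:`UnsupportedFragmentError` for constructs outside the
    fragment — nothing is silently dropped.
    """
    rg = _as_rdflib_graph(ontology_graph)
    node = URIRef(class_iri.value)
    defn = rg.value(node, OWL.equivalentClass)
    if defn is None:
        return NamedClass(class_iri)
    return _parse_expr(rg, defn)


def load_ontology(source: Union[str, Path, rdflib.Graph], dialect: str = "turtle") -> Ontology:
    """Read an ontology document (Turtle or RDF/XML) into an :class:`Ontology`.

    Picks up owl:equivalentClass definitions, rdfs:subClassOf axioms between
    named classes, and rdfs:subPropertyOf axioms.
    """
    if isinstance(source, rdflib.Graph):
        rg = source
    else:
        rg = rdflib.Graph()
        fmt = {"turtle": "turtle", "rdfxml": "xml"}.get(dialect, dialect)
        text = str(source)
        looks_like_path = "\n" not in text and len(text) < 4096
        if isinstance(source, Path) or (looks_like_path and Path(text).exists()):
            rg.parse(Path(text), format=fmt)
        else:
            rg.parse(data=text, format=fmt)

    definitions: Dict[IRI, ClassExpression] = {}
    for s in rg.subjects(OWL.equivalentClass, None):
        if isinstance(s, URIRef):
            definitions[IRI(str(s))] = parse_class_expression(rg, IRI(str(s)))
    subclass = {
        (IRI(str(a)), IRI(str(b)))
        for a, b in rg.subject_objects(RDFS.subClassOf)
        if isinstance(a, URIRef) and isinstance(b, URIRef)
    }
    subprop = {
        (IRI(str(a)), IRI(str(b)))
        for a, b in rg.subject_objects(RDFS.subPropertyOf)
        if isinstance(a, URIRef) and isinstance(b, URIRef)
    }
    return Ontology(definitions, subclass, subprop)


def _expr_to_rdflib(rg: rdflib.Graph, expr: Union[ClassExpression, NumericRange]):
    if isinstance(expr, NamedClass):
        return URIRef(expr.iri.value)
    node = BNode()
    if isinstance(expr, NumericRange):
        if not expr.facet_items:
            return URIRef(expr.datatype.value)
        rg.add((node, RDF.type, RDFS.Datatype))
        rg.add((node, OWL.onDatatype, URIRef(expr.datatype.value)))
        facet_nodes = []
        for name, bound in expr.facet_items:
            fn = BNode()
            rg.add((fn, URIRef(XSD + name), rdflib.Literal(bound)))
            facet_nodes.append(fn)
        rg.add((node, OWL.withRestrictions, _rdflib_list(rg, facet_nodes)))
        return node
    if isinstance(expr, IntersectionOf):
        rg.add((node, RDF.type, OWL.Class))
        members = [_expr_to_rdflib(rg, m) for m in expr.members]
        rg.add((node, OWL.intersectionOf, _rdflib_list(rg, members)))
        return node
    if isinstance(expr, SomeValuesFrom):
        rg.add((node, RDF.type, OWL.Restriction))
        rg.add((node, OWL.onProperty, URIRef(expr.property.value)))
        rg.add((node, OWL.someValuesFrom, _expr_to_rdflib(rg, expr.filler)))
        return node
    if isinstance(expr, HasValue):
        rg.add((node, RDF.type, OWL.Restriction))
        rg.add((node, OWL.onProperty, URIRef(expr.property.value)))
        rg.add((node, OWL.hasValue, _to_rdflib_term(expr.value)))
        return node
    raise GraphError(f"cannot serialize {expr!r}")


def _rdflib_list(rg: rdflib.Graph, items):
    head = RDF.nil
    for item in reversed(items):
        node = BNode()
        rg.add((node, RDF.first, item))
        rg.add((node, RDF.rest, head))
        head = node
    return head


def ontology_to_turtle(ont: Ontology) -> str:
    """Serialize an ontology using standard OWL vocabulary."""
    rg = rdflib.Graph()
    rg.bind("owl", OWL)
    rg.bind("rdfs", RDFS)
    for c, expr in sorted(ont.class_definitions.items()):
        rg.add((URIRef(c.value), RDF.type, OWL.Class))
        rg.add((URIRef(c.value), OWL.equivalentClass, _expr_to_rdflib(rg, expr)))
    for a, b in sorted(ont.subclass_axioms):
        rg.add((URIRef(a.value), RDFS.subClassOf, URIRef(b.value)))
    for a, b in sorted(ont.subproperty_axioms):
        rg.add((URIRef(a.value), RDFS.subPropertyOf, URIRef(b.value)))
    return rg.serialize(format="turtle")


# ---------------------------------------------------------------------------
# Instance reasoning
# ---------------------------------------------------------------------------


def _satisfies_filler(
    g: Graph,
    value: Term,
    filler: Union[ClassExpression, NumericRange, IRI, Literal],
    ont: Ontology,
    visiting: FrozenSet[IRI],
) -> bool:
    if isinstance(filler, NumericRange):
        if not isinstance(value, Literal):
            return False
        num = value.as_decimal()
        if num is None:
            logger.warning(
                "literal %r tested against numeric range on datatype %s is not "
                "a finite number; treating as non-member",
                value.lexical_form,
                filler.datatype.value,
            )
            return False
        return filler.contains(num)
    if isinstance(filler, (IRI, Literal)):  # hasValue
        return value == filler
    if not isinstance(value, IRI):
        return False
    return _entails(g, value, filler, ont, visiting)


def _entails(
    g: Graph,
    ind: IRI,
    expr: ClassExpression,
    ont: Ontology,
    visiting: FrozenSet[IRI],
) -> bool:
    triples = g.by_subject().get(ind, [])
    for req in decompose(expr):
        if isinstance(req, MembershipReq):
            target = req.class_iri
            if target == OWL_THING:
                continue
            asserted = {
                t.object for t in triples if t.predicate == RDF_TYPE and isinstance(t.object, IRI)
            }
            if any(target in ont.superclasses(a) for a in asserted):
                continue
            # the class (or one of its named subclasses) may be defined:
            # membership then follows from the definition
            derived = False
            for cand in ont.subclasses(target):
                defn = ont.class_definitions.get(cand)
                if defn is None or cand in visiting:
                    continue
                if _entails(g, ind, defn, ont, visiting | {cand}):
                    derived = True
                    break
            if not derived:
                return False
        else:
            preds = ont.subproperties(req.property)
            ok = False
            for t in triples:
                if t.predicate in preds and _satisfies_filler(
                    g, t.object, req.filler, ont, visiting
                ):
                    ok = True
                    break
            if not ok:
                return False
    return True


def entails_membership(
    g: Graph, ind: IRI, expr: Union[ClassExpression, IRI], ont: Ontology
) -> bool:
    """Does the graph entail that ``ind`` is a member of ``expr``?

    Pure function over the graph: checks every decomposed requirement —
    type memberships through the subclass hierarchy and class definitions,
    property restrictions through the subproperty hierarchy with recursive
    filler checks.  No services are consulted.
    """
    return _entails(g, ind, ont.resolve(expr), ont, frozenset())


def individuals(g: Graph) -> Set[IRI]:
    """IRIs playing the role of individuals: subjects, plus IRI objects of
    non-``rdf:type`` triples (type objects are classes, not individuals)."""
    out = {t.subject for t in g.triples}
    out |= {
        t.object
        for t in g.triples
        if isinstance(t.object, IRI) and t.predicate != RDF_TYPE
    }
    return out


def classify_all(g: Graph, ont: Ontology, max_iterations: int = 10) -> Graph:
    """Materialize entailed ``rdf:type`` assertions to fixpoint.

    Adds, for every individual, membership in every defined class it
    satisfies, closed upward under the subclass hierarchy.  Definitions may
    cascade (one entailment enabling the next), so the pass iterates until
    nothing new is derived.  Monotone (output ⊇ input) and idempotent.
    """
    current = g
    for _ in range(max_iterations):
        new: Set[Triple] = set()
        inds = individuals(current)
        for ind in inds:
            asserted = {
                t.object
                for t in current.by_subject().get(ind, [])
                if t.predicate == RDF_TYPE and isinstance(t.object, IRI)
            }
            # subclass closure of asserted types
            for a in asserted:
                for sup in ont.superclasses(a):
                    t = Triple(ind, RDF_TYPE, sup)
                    if t not in current.triples:
                        new.add(t)
            # defined-class membership
            for c, defn in ont.class_definitions.items():
                if c in asserted:
                    continue
                if _entails(current, ind, defn, ont, frozenset({c})):
                    for sup in ont.superclasses(c):
                        t = Triple(ind, RDF_TYPE, sup)
                        if t not in current.triples:
                            new.add(t)
        if not new:
            return current
        current = current.merge(Graph(frozenset(new)))
    raise FixpointError(
        f"classification did not reach a fixpoint within {max_iterations} "
        "iterations; check class definitions for a cycle"
    )
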