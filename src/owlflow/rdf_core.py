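"""Minimal RDF data model: IRIs, literals, triples, and immutable graphs.

Every other layer of the package exchanges data through the :class:`Graph`
type defined here — a frozen *set* of triples, so that merging service
outputs into the working graph is plain set union (commutative, associative,
idempotent).  Parsing, serialization and SPARQL evaluation are delegated to
rdflib; this module pins down the semantics the rest of the system relies
on:

* subjects are always named IRIs — blank-node subjects are rejected, because
  the annotation-service contract (input and output individuals share one
  URI) is unverifiable for unnamed nodes;
* numeric literals compare by value: every xsd numeric datatype is promoted
  to arbitrary-precision :class:`~decimal.Decimal` before comparison, so
  ``"1.0"^^xsd:decimal`` and ``"1"^^xsd:integer`` denote the same node
  regardless of which serialization produced them.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import rdflib
from rdflib import BNode, URIRef
from rdflib.plugins.sparql import prepareQuery

__all__ = [
    "IRI",
    "Literal",
    "Triple",
    "Graph",
    "BindingsTable",
    "EMPTY_GRAPH",
    "XSD",
    "RDF_TYPE",
    "GraphError",
    "BlankNodeSubjectError",
    "ParseError",
    "QueryError",
    "load_graph",
    "loads_graph",
    "save_graph",
    "merge",
    "evaluate_sparql",
]

XSD = "http://www.w3.org/2001/XMLSchema#"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"

#: xsd datatypes whose literals are compared numerically.
NUMERIC_DATATYPES = frozenset(
    XSD + local
    for local in (
        "decimal", "integer", "int", "long", "short", "byte", "double",
        "float", "nonNegativeInteger", "nonPositiveInteger",
        "positiveInteger", "negativeInteger", "unsignedLong", "unsignedInt",
        "unsignedShort", "unsignedByte",
    )
)


class GraphError(ValueError):
    """Base class for RDF-layer errors."""


class BlankNodeSubjectError(GraphError):
    """Raised when instance data contains a blank-node subject."""


class ParseError(GraphError):
    """Raised when a document cannot be parsed in the named dialect."""


class QueryError(GraphError):
    """Raised for syntactically invalid SPARQL."""


@dataclass(frozen=True, order=True)
class IRI:
    """An absolute IRI, usable as subject, predicate, or object."""

    value: str

    def __post_init__(self) -> None:
        if not self.value:
            raise GraphError("IRI must be non-empty")
        scheme, sep, _ = self.value.partition(":")
        if not sep or not scheme or not scheme[0].isalpha():
            raise GraphError(f"IRI must be absolute (have a scheme): {self.value!r}")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.value


XSD_STRING = IRI(XSD + "string")
XSD_DECIMAL = IRI(XSD + "decimal")
XSD_DATETIME = IRI(XSD + "dateTime")
RDF_TYPE = IRI(RDF_NS + "type")


@dataclass(frozen=True)
class Literal:
    """A typed RDF literal.

    Numeric-datatype literals must parse to finite numbers and compare (and
    hash) by numeric value; all other literals compare by lexical form and
    datatype.
    """

    lexical_form: str
    datatype: IRI = XSD_STRING

    def __post_init__(self) -> None:
        if self.is_numeric and self.as_decimal() is None:
            raise GraphError(
                f"literal {self.lexical_form!r} is not a finite number for "
                f"datatype {self.datatype.value}"
            )

    @property
    def is_numeric(self) -> bool:
        return self.datatype.value in NUMERIC_DATATYPES

    def as_decimal(self) -> Optional[Decimal]:
        """The numeric value as a Decimal, or None if not finite numeric."""
        if self.datatype.value not in NUMERIC_DATATYPES:
            return None
        lex = self.lexical_form.strip()
        try:
            d = Decimal(lex)
        except InvalidOperation:
            return None
        if not d.is_finite():
            return None
        return d

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Literal):
            return NotImplemented
        a, b = self.as_decimal(), other.as_decimal()
        if a is not None and b is not None:
            return a == b
        return (self.lexical_form, self.datatype) == (
            other.lexical_form,
            other.datatype,
        )

    def __hash__(self) -> int:
        d = self.as_decimal()
        if d is not None:
            return hash(d)
        return hash((self.lexical_form, self.datatype))


Term = Union[IRI, Literal]


def decimal_literal(value) -> Literal:
    """An xsd:decimal literal from an int, float, Decimal, or string."""
    if isinstance(value, float):
        value = Decimal(repr(value))
    return Literal(str(value), XSD_DECIMAL)


@dataclass(frozen=True, order=True)
class Triple:
    """A single RDF statement; subject and predicate are always IRIs."""

    subject: IRI
    predicate: IRI
    object: Term

    def __post_init__(self) -> None:
        if not isinstance(self.subject, IRI):
            raise GraphError(f"triple subject must be an IRI, got {self.subject!r}")
        if not isinstance(self.predicate, IRI):
            raise GraphError(f"triple predicate must be an IRI, got {self.predicate!r}")
        if not isinstance(self.object, (IRI, Literal)):
            raise GraphError(f"triple object must be IRI or Literal, got {self.object!r}")


def _term_sort_key(t: Term):
    if isinstance(t, IRI):
        return (0, t.value, "")
    return (1, t.lexical_form, t.datatype.value)


@dataclass(frozen=True)
class Graph:
    """An immutable set of triples; merge is set union."""

    triples: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "triples", frozenset(self.triples))

    def __len__(self) -> int:
        return len(self.triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(self.sorted_triples())

    def __contains__(self, t: Triple) -> bool:
        return t in self.triples

    def sorted_triples(self) -> list:
        cached = getattr(self, "_sorted", None)
        if cached is None:
            cached = sorted(
                self.triples,
                key=lambda t: (t.subject.value, t.predicate.value, _term_sort_key(t.object)),
            )
            object.__setattr__(self, "_sorted", cached)
        return cached

    def by_subject(self) -> dict:
        """Subject → sorted list of triples; cached (graphs are immutable)."""
        cached = getattr(self, "_by_subject", None)
        if cached is None:
            cached = {}
            for t in self.sorted_triples():
                cached.setdefault(t.subject, []).append(t)
            object.__setattr__(self, "_by_subject", cached)
        return cached

    def merge(self, other: "Graph") -> "Graph":
        return Graph(self.triples | other.triples)

    def __or__(self, other: "Graph") -> "Graph":
        return self.merge(other)

    def add(self, *triples: Triple) -> "Graph":
        return Graph(self.triples | set(triples))

    def difference(self, other: "Graph") -> "Graph":
        return Graph(self.triples - other.triples)

    def match(
        self,
        subject: Optional[IRI] = None,
        predicate: Optional[IRI] = None,
        obj: Optional[Term] = None,
    ) -> Iterator[Triple]:
        """All triples matching the given pattern (None = wildcard)."""
        for t in self.sorted_triples():
            if subject is not None and t.subject != subject:
                continue
            if predicate is not None and t.predicate != predicate:
                continue
            if obj is not None and t.object != obj:
                continue
            yield t

    def subjects(self) -> set:
        return {t.subject for t in self.triples}

    def named_nodes(self) -> set:
        """Every IRI occurring in subject or object position (the individuals)."""
        nodes = {t.subject for t in self.triples}
        nodes |= {t.object for t in self.triples if isinstance(t.object, IRI)}
        return nodes

    def objects(self, subject: IRI, predicate: IRI) -> list:
        return [t.object for t in self.match(subject, predicate)]

    def value(self, subject: IRI, predicate: IRI) -> Optional[Term]:
        objs = self.objects(subject, predicate)
        return objs[0] if objs else None


EMPTY_GRAPH = Graph()


def merge(a: Graph, b: Graph) -> Graph:
    """Set union of two graphs."""
    return a.merge(b)


def graph_of(triples: Iterable[Triple]) -> Graph:
    return Graph(frozenset(triples))


# ---------------------------------------------------------------------------
# rdflib bridge
# ---------------------------------------------------------------------------

_DIALECTS = {"turtle": "turtle", "rdfxml": "xml"}


def _to_rdflib_term(t: Term):
    if isinstance(t, IRI):
        return URIRef(t.value)
    return rdflib.Literal(t.lexical_form, datatype=URIRef(t.datatype.value))


def _from_rdflib_term(t) -> Term:
    if isinstance(t, URIRef):
        return IRI(str(t))
    if isinstance(t, rdflib.Literal):
        dt = IRI(str(t.datatype)) if t.datatype else XSD_STRING
        return Literal(str(t), dt)
    raise BlankNodeSubjectError(
        "blank nodes are not supported in instance data: the same-URI "
        "service contract requires every individual to have a stable name"
    )


def to_rdflib(g: Graph) -> rdflib.Graph:
    rg = rdflib.Graph()
    for t in g.triples:
        rg.add((URIRef(t.subject.value), URIRef(t.predicate.value), _to_rdflib_term(t.object)))
    return rg


def from_rdflib(rg: rdflib.Graph, allow_bnodes: bool = False) -> Graph:
    """Convert an rdflib graph; blank-node subjects are rejected.

    ``allow_bnodes=True`` skips triples involving blank nodes instead of
    erroring — used only when reading ontology documents, whose OWL list
    structure legitimately uses blank nodes and is consumed by the ontology
    parser directly from rdflib.
    """
    triples = set()
    for s, p, o in rg:
        if isinstance(s, BNode) or isinstance(o, BNode):
            if allow_bnodes:
                continue
            if isinstance(s, BNode):
                raise BlankNodeSubjectError(
                    f"blank-node subject in instance data (near predicate {p}): "
                    "individuals must have stable IRIs for the same-URI "
                    "service contract to be checkable"
                )
            raise BlankNodeSubjectError(
                f"blank-node object in instance data (subject {s}): "
                "unnamed nodes cannot be re-identified across services"
            )
        triples.add(Triple(IRI(str(s)), IRI(str(p)), _from_rdflib_term(o)))
    return Graph(frozenset(triples))


def loads_graph(text: str, dialect: str = "turtle") -> Graph:
    """Parse a serialized RDF document from a string."""
    if dialect not in _DIALECTS:
        raise GraphError(f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}")
    rg = rdflib.Graph()
    try:
        rg.parse(data=text, format=_DIALECTS[dialect])
    except Exception as exc:  # rdflib raises dialect-specific classes
        raise ParseError(f"cannot parse {dialect} document: {exc}") from exc
    return from_rdflib(rg)


def load_graph(source: Union[str, Path], dialect: Optional[str] = None) -> Graph:
    """Load a graph from a file path; dialect inferred from suffix if omitted.

    ``.ttl`` → turtle, ``.rdf``/``.xml`` → rdfxml.
    """
    path = Path(source)
    if dialect is None:
        dialect = {"ttl": "turtle", "rdf": "rdfxml", "xml": "rdfxml"}.get(
            path.suffix.lstrip("."), "turtle"
        )
    return loads_graph(path.read_text(), dialect)


def _turtle_term(t: Term) -> str:
    if isinstance(t, IRI):
        return f"<{t.value}>"
    lex = (
        t.lexical_form.replace("\\", "\\\\")
        .replace('"', '\\"')
        .replace("\n", "\\n")
        .replace("\r", "\\r")
        .replace("\t", "\\t")
    )
    return f'"{lex}"^^<{t.datatype.value}>'


def save_graph(g: Graph, dialect: str = "turtle") -> str:
    """Serialize a graph.

    Turtle output is deterministic: one statement per line, sorted — so a
    graph serializes to the same bytes on every run (fixtures are
    reproducible byte-for-byte).  RDF/XML goes through rdflib and is
    guaranteed only to round-trip as a set.
    """
    if dialect == "turtle":
        lines = [
            f"{_turtle_term(t.subject)} {_turtle_term(t.predicate)} {_turtle_term(t.object)} ."
            for t in g.sorted_triples()
        ]
        return "\n".join(lines) + ("\n" if lines else "")
    if dialect == "rdfxml":
        return to_rdflib(g).serialize(format="xml")
    raise GraphError(f"unknown dialect {dialect!r}")


def write_graph(g: Graph, path: Union[str, Path], dialect: str = "turtle") -> None:
    Path(path).write_text(save_graph(g, dialect))


# ---------------------------------------------------------------------------
# SPARQL
# ---------------------------------------------------------------------------


class BindingsTable:
    """The result of a SELECT query: variable names plus rows of bindings.

    Row order is unspecified; equality compares rows as multisets.
    """

    def __init__(self, variables: Sequence[str], rows: Iterable[Mapping[str, Optional[Term]]]):
        self.variables = list(variables)
        self.rows = [dict(r) for r in rows]

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def _multiset(self):
        key = lambda row: tuple(sorted((v, repr(t)) for v, t in row.items()))
        return sorted(key(r) for r in self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BindingsTable):
            return NotImplemented
        return set(self.variables) == set(other.variables) and self._multiset() == other._multiset()

    def __repr__(self) -> str:
        return f"BindingsTable(vars={self.variables}, nrows={len(self.rows)})"

    def to_csv(self) -> str:
        """SPARQL-results CSV: header of variable names, one row per solution."""
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(self.variables)
        for row in self.rows:
            w.writerow(
                [
                    ""
                    if row.get(v) is None
                    else (row[v].value if isinstance(row[v], IRI) else row[v].lexical_form)
                    for v in self.variables
                ]
            )
        return buf.getvalue()


def prepare_query(query: str):
    """Parse a SPARQL SELECT query, raising QueryError with position info."""
    try:
        pq = prepareQuery(query)
    except Exception as exc:
        raise QueryError(f"malformed SPARQL query: {exc}") from exc
    if pq.algebra.name != "SelectQuery":
        raise QueryError("only SELECT queries are supported")
    return pq


def evaluate_sparql(g: Graph, query: str) -> BindingsTable:
    """Standard SPARQL 1.1 SELECT evaluation over ``g`` only.

    No services are invoked and no inference happens here.  A single FROM
    clause is honored by resolving it to ``g`` itself (the caller decides
    which local document the named dataset denotes).
    """
    pq = prepare_query(query)
    rg = to_rdflib(g)
    result = rg.query(pq)
    variables = [str(v) for v in result.vars] if result.vars else []
    rows = []
    for binding in result:
        row = {}
        for var in variables:
            val = binding[var] if var in binding.asdict() else None
            row[var] = None if val is None else _from_rdflib_term(val)
        rows.append(row)
    return BindingsTable(variables, rows)
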