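"""Service registry: index annotation services and answer discovery queries.

Two discovery axes mirror how a query engine looks for help:

* **by predicate** — "which service can attach ``latestBUN``?"  The index
  stores each attached property under itself *and* its declared
  superproperties, so discovery by a more general predicate succeeds
  (agreement on predicates, not on classes, is what the ecosystem needs).
* **by consumable class** — "which services could run on an individual of
  this class?"  Matching is requirement coverage under subclass/subproperty
  closure: a sound, decidable approximation of TBox subsumption that stays
  inside the supported fragment.

The whole index exports as an RDF graph, so discovery can equally be done
with plain SPARQL over the published descriptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Dict, FrozenSet, List, Optional, Set, Union

from .rdf_core import Graph, IRI, Literal
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
from .service_model import (
    Implementation,
    SVC_SERVICE,
    ServiceDescription,
    attached_properties,
    describe,
    interpret_description,
)
from .rdf_core import RDF_TYPE

__all__ = ["Registry", "RegistryError", "export_registry_graph", "import_registry"]


class RegistryError(ValueError):
    pass


@dataclass
class Registry:
    """In-memory service index over a shared ontology."""

    ontology: Ontology
    services: Dict[IRI, ServiceDescription] = field(default_factory=dict)
    predicate_index: Dict[IRI, Set[IRI]] = field(default_factory=dict)

    def _rebuild_index(self) -> None:
        self.predicate_index = {}
        for s in self.services.values():
            for p in attached_properties(s, self.ontology):
                for sup in self.ontology.superproperties(p):
                    self.predicate_index.setdefault(sup, set()).add(s.iri)

    def register(self, s: ServiceDescription) -> "Registry":
        """Add a service (idempotent by IRI; conflicting re-registration of
        the same IRI with a different interface is an error)."""
        existing = self.services.get(s.iri)
        if existing is not None:
            if existing.same_interface(s):
                # no-op re-registration; keep whichever has an implementation
                if existing.implementation is None and s.implementation is not None:
                    self.services[s.iri] = s
                return self
            raise RegistryError(
                f"service {s.iri.value} already registered with a different interface"
            )
        self.services[s.iri] = s
        self._rebuild_index()
        return self

    def deregister(self, iri: IRI) -> "Registry":
        self.services.pop(iri, None)
        self._rebuild_index()
        return self

    def get(self, iri: IRI) -> Optional[ServiceDescription]:
        return self.services.get(iri)

    def __len__(self) -> int:
        return len(self.services)

    def find_by_predicate(self, p: IRI) -> List[ServiceDescription]:
        """Services able to attach ``p`` (directly or via a declared
        subproperty), in deterministic order by service IRI."""
        iris = self.predicate_index.get(p, set())
        return [self.services[i] for i in sorted(iris)]

    def find_consuming(self, available: Union[IRI, ClassExpression]) -> List[ServiceDescription]:
        """Services whose input class an individual of ``available`` would
        satisfy, by requirement coverage under the closures."""
        out = [
            s
            for s in self.services.values()
            if _covers(self.ontology, available, s.input_class)
        ]
        return sorted(out, key=lambda s: s.iri)

    def attached_predicates(self) -> Set[IRI]:
        """Every predicate any registered service can attach (pre-closure)."""
        preds: Set[IRI] = set()
        for s in self.services.values():
            preds |= attached_properties(s, self.ontology)
        return preds


# ---------------------------------------------------------------------------
# requirement-coverage matching
# ---------------------------------------------------------------------------


def _granted_requirements(ont: Ontology, expr: ClassExpression) -> List[Requirement]:
    """Everything an individual of ``expr`` is guaranteed to satisfy:
    the decomposed requirements, closed under class definitions (equivalence
    works both ways) and upward under the subclass hierarchy."""
    grants: List[Requirement] = []
    seen: Set[Requirement] = set()
    agenda = list(decompose(expr))
    expanded: Set[IRI] = set()
    while agenda:
        req = agenda.pop(0)
        if req in seen:
            continue
        seen.add(req)
        grants.append(req)
        if isinstance(req, MembershipReq):
            for sup in ont.superclasses(req.class_iri):
                sup_req = MembershipReq(sup)
                if sup_req not in seen:
                    agenda.append(sup_req)
            defn = ont.class_definitions.get(req.class_iri)
            if defn is not None and req.class_iri not in expanded:
                expanded.add(req.class_iri)
                agenda.extend(decompose(defn))
    return grants


def _range_subsumes(outer: NumericRange, inner: NumericRange) -> bool:
    """Is every value of ``inner`` inside ``outer``?  Conservative bound
    comparison; datatypes are not compared (numeric promotion semantics)."""
    fo, fi = outer.facets, inner.facets

    def lo(f):
        if "minInclusive" in f:
            return (f["minInclusive"], True)
        if "minExclusive" in f:
            return (f["minExclusive"], False)
        return None

    def hi(f):
        if "maxInclusive" in f:
            return (f["maxInclusive"], True)
        if "maxExclusive" in f:
            return (f["maxExclusive"], False)
        return None

    olo, ilo = lo(fo), lo(fi)
    if olo is not None:
        if ilo is None:
            return False
        if ilo[0] < olo[0] or (ilo[0] == olo[0] and ilo[1] and not olo[1]):
            return False
    ohi, ihi = hi(fo), hi(fi)
    if ohi is not None:
        if ihi is None:
            return False
        if ihi[0] > ohi[0] or (ihi[0] == ohi[0] and ihi[1] and not ohi[1]):
            return False
    return True


def _filler_covers(ont: Ontology, granted_filler, needed_filler) -> bool:
    if isinstance(needed_filler, NumericRange):
        if isinstance(granted_filler, NumericRange):
            return _range_subsumes(needed_filler, granted_filler)
        if isinstance(granted_filler, Literal):
            d = granted_filler.as_decimal()
            return d is not None and needed_filler.contains(d)
        return False
    if isinstance(needed_filler, (IRI, Literal)):  # hasValue need
        return granted_filler == needed_filler
    # needed filler is a class expression
    if isinstance(granted_filler, (NumericRange, IRI, Literal)):
        return False
    return _requirements_covered(ont, _granted_requirements(ont, granted_filler), needed_filler, set())


def _requirements_covered(
    ont: Ontology,
    grants: List[Requirement],
    needed_expr: ClassExpression,
    visiting: Set[IRI],
) -> bool:
    for need in decompose(needed_expr):
        if isinstance(need, MembershipReq):
            target = need.class_iri
            if target == OWL_THING:
                continue
            granted_classes = {
                g.class_iri for g in grants if isinstance(g, MembershipReq)
            }
            if target in granted_classes:
                continue
            defn = ont.class_definitions.get(target)
            if (
                defn is not None
                and target not in visiting
                and _requirements_covered(ont, grants, defn, visiting | {target})
            ):
                continue
            return False
        else:
            ok = False
            for g in grants:
                if not isinstance(g, PropertyReq):
                    continue
                if need.property not in ont.superproperties(g.property):
                    continue
                if _filler_covers(ont, g.filler, need.filler):
                    ok = True
                    break
            if not ok:
                return False
    return True


def _covers(
    ont: Ontology,
    available: Union[IRI, ClassExpression],
    needed: Union[IRI, ClassExpression],
) -> bool:
    avail_expr = ont.resolve(available)
    needed_expr = ont.resolve(needed)
    return _requirements_covered(
        ont, _granted_requirements(ont, avail_expr), needed_expr, set()
    )


# ---------------------------------------------------------------------------
# RDF export / import
# ---------------------------------------------------------------------------


def export_registry_graph(r: Registry) -> Graph:
    """Union of every registered service's published description; plain
    SPARQL over this graph reproduces predicate discovery."""
    g = Graph()
    for iri in sorted(r.services):
        g = g.merge(describe(r.services[iri], r.ontology))
    return g


def import_registry(
    g: Graph,
    ontology: Ontology,
    implementations: Optional[Dict[IRI, Implementation]] = None,
) -> Registry:
    """Rebuild a registry from an exported description graph.  Implementation
    callables are rebound by service IRI from ``implementations``."""
    implementations = implementations or {}
    reg = Registry(ontology=ontology)
    service_iris = sorted(
        {t.subject for t in g.match(None, RDF_TYPE, SVC_SERVICE)}
    )
    for iri in service_iris:
        reg.register(interpret_description(g, iri, implementations.get(iri)))
    return reg
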