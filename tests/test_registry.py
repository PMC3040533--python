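"""Service indexing and discovery by predicate / class compatibility."""

import random
from decimal import Decimal

import pytest

import owlflow.demo_domain as dd
from owlflow.rdf_core import Graph, IRI, RDF_TYPE, Triple, decimal_literal, evaluate_sparql
from owlflow.ontology_core import (
    IntersectionOf,
    MembershipReq,
    NamedClass,
    NumericRange,
    Ontology,
    PropertyReq,
    SomeValuesFrom,
    decompose,
    entails_membership,
)
from owlflow.registry import Registry, RegistryError, export_registry_graph, import_registry
from owlflow.service_model import SVC_ATTACHES, ServiceDescription, attached_properties

from conftest import ex


class TestRegister:
    def test_register_then_lookup(self, registry):
        svc = dd.regression_service()
        assert registry.get(svc.iri).same_interface(svc)

    def test_reregister_identical_is_noop(self, registry):
        n = len(registry)
        registry.register(dd.regression_service())
        assert len(registry) == n

    def test_reregister_conflicting_interface_errors(self, registry, ontology):
        svc = dd.regression_service()
        conflicting = ServiceDescription(
            iri=svc.iri,
            name=svc.name,
            input_class=dd.PATIENT,  # different input class, same IRI
            output_class=svc.output_class,
        )
        with pytest.raises(RegistryError):
            registry.register(conflicting)

    def test_demo_index_covers_exactly_the_attached_predicates(self, registry, ontology):
        # brute-force union of attached_properties over all services
        want = set()
        for s in registry.services.values():
            want |= attached_properties(s, ontology)
        assert want == {dd.HAS_REGRESSION_MODEL, dd.LATEST_BUN, dd.LATEST_CREATININE}
        indexed = set(registry.predicate_index)
        assert indexed == want | {dd.LATEST_MEASUREMENT}  # + superproperties

    def test_every_attached_property_is_findable(self, registry, ontology):
        for s in registry.services.values():
            for p in attached_properties(s, ontology):
                assert s.iri in {m.iri for m in registry.find_by_predicate(p)}


class TestFindByPredicate:
    def test_unknown_predicate_empty(self, registry):
        assert registry.find_by_predicate(ex("nothing")) == []

    def test_latest_bun_finds_the_bun_service(self, registry):
        found = registry.find_by_predicate(dd.LATEST_BUN)
        assert [s.iri.value.rsplit("#")[-1] for s in found] == ["latest-bun"]

    def test_superproperty_lookup_includes_subproperty_services(self, registry):
        general = {s.iri for s in registry.find_by_predicate(dd.LATEST_MEASUREMENT)}
        specific = {s.iri for s in registry.find_by_predicate(dd.LATEST_CREATININE)}
        assert specific <= general
        assert len(general) == 2  # both latest-value services


# ---------------------------------------------------------------------------
# find_consuming
# ---------------------------------------------------------------------------


def canonical_individual(expr, ont, base="http://e/canon"):
    """Instantiate a minimal individual of ``expr``: the membership oracle
    for class-compatibility matching."""
    triples = set()
    counter = [0]

    def witness(nr: NumericRange) -> Decimal:
        f = nr.facets
        lo = f.get("minInclusive", f.get("minExclusive"))
        hi = f.get("maxInclusive", f.get("maxExclusive"))
        if lo is None and hi is None:
            return Decimal(0)
        if lo is None:
            return hi - 1
        if hi is None:
            return lo + (1 if "minExclusive" in f else 0)
        return (lo + hi) / 2

    def build(node: IRI, e) -> None:
        for req in decompose(e):
            if isinstance(req, MembershipReq):
                triples.add(Triple(node, RDF_TYPE, req.class_iri))
                defn = ont.class_definitions.get(req.class_iri)
                if defn is not None:
                    build(node, defn)
            else:
                filler = req.filler
                if isinstance(filler, NumericRange):
                    triples.add(Triple(node, req.property, decimal_literal(witness(filler))))
                elif isinstance(filler, (IRI,)):
                    triples.add(Triple(node, req.property, filler))
                elif hasattr(filler, "lexical_form"):
                    triples.add(Triple(node, req.property, filler))
                else:
                    counter[0] += 1
                    child = IRI(f"{base}/n{counter[0]}")
                    triples.add(Triple(node, req.property, child))
                    build(child, filler)

    root = IRI(base)
    build(root, ont.resolve(expr))
    return root, Graph(frozenset(triples))


def random_classonly_expression(rng, ont_classes, props, depth):
    kind = rng.choice(["named"] if depth == 0 else ["named", "inter", "some"])
    if kind == "named":
        return NamedClass(rng.choice(ont_classes))
    if kind == "inter":
        return IntersectionOf(
            tuple(
                random_classonly_expression(rng, ont_classes, props, depth - 1)
                for _ in range(2)
            )
        )
    return SomeValuesFrom(
        rng.choice(props), random_classonly_expression(rng, ont_classes, props, depth - 1)
    )


class TestFindConsuming:
    def test_subclass_axiom_lets_timecourse_feed_regression(self, registry):
        """A blood-chemistry time-course is a specialized kind of X-Y
        coordinate data, so the regression service consumes it."""
        found = registry.find_consuming(dd.BLOOD_CHEMISTRY_TIME_COURSE)
        assert dd.regression_service().iri in {s.iri for s in found}

    def test_top_class_feeds_nothing_in_demo_registry(self, registry):
        from owlflow.ontology_core import OWL_THING

        assert registry.find_consuming(NamedClass(OWL_THING)) == []

    def test_matches_canonical_individual_oracle_on_random_registries(self, ontology):
        classes = [ex(f"K{i}") for i in range(4)]
        props = [ex(f"q{i}") for i in range(3)]
        rng = random.Random(2024)
        checked_positive = 0
        for trial in range(30):
            subclass = set()
            for _ in range(rng.randint(0, 3)):
                a, b = rng.sample(classes, 2)
                if (b, a) not in subclass:
                    subclass.add((a, b))
            try:
                ont = Ontology({}, subclass, set())
            except Exception:
                continue
            reg = Registry(ontology=ont)
            inputs = {}
            for k in range(3):
                iri = ex(f"svc{trial}_{k}")
                inp = random_classonly_expression(rng, classes, props, 2)
                out = IntersectionOf((inp, SomeValuesFrom(ex(f"out{k}"), NamedClass(classes[0]))))
                reg.register(ServiceDescription(iri, f"s{k}", inp, out))
                inputs[iri] = inp
            available = random_classonly_expression(rng, classes, props, 2)
            got = {s.iri for s in reg.find_consuming(available)}
            root, canon = canonical_individual(available, ont)
            want = {
                iri
                for iri, inp in inputs.items()
                if entails_membership(canon, root, inp, ont)
            }
            assert got == want, (available, inputs)
            checked_positive += len(want)
        assert checked_positive > 5


class TestExport:
    def test_empty_registry_exports_empty_graph(self, ontology):
        assert len(export_registry_graph(Registry(ontology=ontology))) == 0

    def test_sparql_over_export_matches_find_by_predicate(self, registry, ontology):
        g = export_registry_graph(registry)
        for p in [dd.HAS_REGRESSION_MODEL, dd.LATEST_CREATININE, dd.LATEST_MEASUREMENT]:
            q = f"SELECT ?s WHERE {{ ?s <{SVC_ATTACHES.value}> <{p.value}> }}"
            via_sparql = {row["s"] for row in evaluate_sparql(g, q)}
            via_index = {s.iri for s in registry.find_by_predicate(p)}
            assert via_sparql == via_index

    def test_export_reimport_round_trip(self, registry, ontology):
        g = export_registry_graph(registry)
        impls = {s.iri: s.implementation for s in registry.services.values()}
        back = import_registry(g, ontology, impls)
        assert set(back.services) == set(registry.services)
        for iri, s in registry.services.items():
            assert back.get(iri).same_interface(s)
            assert back.get(iri).implementation is s.implementation
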