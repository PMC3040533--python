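"""Class-expression parsing, decomposition, and instance reasoning."""

import random
from decimal import Decimal

import pytest

import owlflow.demo_domain as dd
from owlflow.rdf_core import Graph, IRI, RDF_TYPE, Triple, decimal_literal
from owlflow.ontology_core import (
    CyclicDefinitionError,
    FixpointError,
    HasValue,
    IntersectionOf,
    MembershipReq,
    NamedClass,
    NumericRange,
    Ontology,
    PropertyReq,
    SomeValuesFrom,
    UnsupportedFragmentError,
    classify_all,
    decompose,
    entails_membership,
    load_ontology,
    ontology_to_turtle,
    parse_class_expression,
)

from conftest import (
    BASE_CLASSES,
    ex,
    random_expression,
    random_instance_graph,
    random_ontology,
)
from _oracles import model_check_membership, model_check_types


class TestParsing:
    def test_primitive_class_parses_as_named(self, ontology):
        ttl = "<http://e/C> a <http://www.w3.org/2002/07/owl#Class> ."
        import rdflib

        rg = rdflib.Graph()
        rg.parse(data=ttl, format="turtle")
        assert parse_class_expression(rg, IRI("http://e/C")) == NamedClass(IRI("http://e/C"))

    def test_demo_likely_rejecter_structure(self, ontology):
        """LikelyRejecter = Patient ⊓ ∃hasCreatinineCollection.ElevatedLevels."""
        ont = load_ontology(ontology_to_turtle(ontology))
        expr = ont.class_definitions[dd.LIKELY_REJECTER]
        assert expr == IntersectionOf(
            (
                NamedClass(dd.PATIENT),
                SomeValuesFrom(dd.HAS_CREATININE_COLLECTION, NamedClass(dd.ELEVATED_LEVELS)),
            )
        )

    def test_demo_increasing_model_has_strict_positive_slope_facet(self, ontology):
        ont = load_ontology(ontology_to_turtle(ontology))
        expr = ont.class_definitions[dd.INCREASING_MODEL]
        assert expr == IntersectionOf(
            (
                NamedClass(dd.LINEAR_REGRESSION_MODEL),
                SomeValuesFrom(
                    dd.SLOPE,
                    NumericRange.of(
                        IRI("http://www.w3.org/2001/XMLSchema#decimal"), minExclusive=0
                    ),
                ),
            )
        )

    @pytest.mark.parametrize(
        "construct",
        ["owl:allValuesFrom <http://e/C>", "owl:unionOf ( <http://e/C> )", "owl:complementOf <http://e/C>"],
    )
    def test_unsupported_constructs_raise_naming_the_construct(self, construct):
        ttl = f"""
        @prefix owl: <http://www.w3.org/2002/07/owl#> .
        <http://e/X> owl:equivalentClass [ owl:onProperty <http://e/p> ; {construct} ] .
        """
        name = construct.split()[0].split(":")[1]
        with pytest.raises(UnsupportedFragmentError, match=name):
            load_ontology(ttl)

    def test_ontology_round_trip(self, ontology):
        reloaded = load_ontology(ontology_to_turtle(ontology))
        assert reloaded.class_definitions == ontology.class_definitions
        assert reloaded.subclass_axioms == ontology.subclass_axioms
        assert reloaded.subproperty_axioms == ontology.subproperty_axioms


class TestHierarchies:
    def test_cyclic_subclass_hierarchy_rejected(self):
        with pytest.raises(CyclicDefinitionError):
            Ontology({}, {(ex("A"), ex("B")), (ex("B"), ex("A"))}, set())

    def test_reflexive_subclass_axiom_tolerated(self):
        ont = Ontology({}, {(ex("A"), ex("A")), (ex("A"), ex("B"))}, set())
        assert ont.superclasses(ex("A")) == {ex("A"), ex("B")}

    def test_cyclic_definitions_rejected(self):
        with pytest.raises(CyclicDefinitionError):
            Ontology(
                {
                    ex("A"): IntersectionOf((NamedClass(ex("B")), NamedClass(ex("C")))),
                    ex("B"): IntersectionOf((NamedClass(ex("A")), NamedClass(ex("C")))),
                },
                set(),
                set(),
            )


class TestDecompose:
    def test_atomic_class(self):
        assert decompose(NamedClass(ex("C"))) == [MembershipReq(ex("C"))]

    def test_likely_rejecter_requirements(self, ontology):
        reqs = decompose(ontology.class_definitions[dd.LIKELY_REJECTER])
        assert reqs == [
            MembershipReq(dd.PATIENT),
            PropertyReq(dd.HAS_CREATININE_COLLECTION, NamedClass(dd.ELEVATED_LEVELS)),
        ]

    def test_nested_intersections_flatten_in_document_order(self):
        a, b, c = (NamedClass(ex(n)) for n in "ABC")
        expr = IntersectionOf((IntersectionOf((a, b)), c))
        assert decompose(expr) == [
            MembershipReq(ex("A")),
            MembershipReq(ex("B")),
            MembershipReq(ex("C")),
        ]

    def test_flattening_preserves_meaning_on_instance_data(self):
        """Decompose/recompose: conjunction of requirements entails and is
        entailed by the original expression — checked by enumerating all
        2^3 type combinations of three atoms."""
        a, b, c = (NamedClass(ex(n)) for n in "ABC")
        expr = IntersectionOf((IntersectionOf((a, b)), c))
        flat = IntersectionOf(tuple(NamedClass(r.class_iri) for r in decompose(expr)))
        ont = Ontology()
        ind = ex("i")
        for mask in range(8):
            triples = {
                Triple(ind, RDF_TYPE, ex("ABC"[k])) for k in range(3) if mask & (1 << k)
            }
            g = Graph(frozenset(triples))
            assert entails_membership(g, ind, expr, ont) == entails_membership(
                g, ind, flat, ont
            )

    def test_has_value_becomes_property_requirement(self):
        expr = HasValue(ex("p"), ex("v"))
        assert decompose(expr) == [PropertyReq(ex("p"), ex("v"))]


class TestEntailment:
    @pytest.fixture()
    def increasing(self, ontology):
        return ontology.class_definitions[dd.INCREASING_MODEL]

    def _model(self, slope: str) -> Graph:
        m = ex("model")
        return Graph(
            frozenset(
                {
                    Triple(m, RDF_TYPE, dd.LINEAR_REGRESSION_MODEL),
                    Triple(m, dd.SLOPE, decimal_literal(slope)),
                }
            )
        )

    def test_positive_slope_is_increasing(self, ontology, increasing):
        assert entails_membership(self._model("0.5"), ex("model"), increasing, ontology)

    def test_zero_slope_is_not_increasing_strict_boundary(self, ontology, increasing):
        assert not entails_membership(self._model("0"), ex("model"), increasing, ontology)

    def test_non_numeric_literal_fails_range_without_raising(self, ontology, increasing):
        m = ex("model")
        g = Graph(
            frozenset(
                {
                    Triple(m, RDF_TYPE, dd.LINEAR_REGRESSION_MODEL),
                    Triple(m, dd.SLOPE, __import__("owlflow.rdf_core", fromlist=["Literal"]).Literal("up")),
                }
            )
        )
        assert entails_membership(g, m, increasing, ontology) is False

    def test_subproperty_closure_applies_to_property_requirements(self):
        ont = Ontology({}, set(), {(ex("psub"), ex("p"))})
        g = Graph(frozenset({Triple(ex("i"), ex("psub"), ex("j"))}))
        expr = SomeValuesFrom(ex("p"), NamedClass(IRI("http://www.w3.org/2002/07/owl#Thing")))
        assert entails_membership(g, ex("i"), expr, ont)

    def test_agrees_with_brute_force_model_checker(self):
        rng = random.Random(42)
        agree_true = 0
        for _ in range(100):
            ont = random_ontology(rng)
            g = random_instance_graph(rng, n_individuals=8)
            expr = random_expression(rng, depth=3)
            for ind in sorted(g.subjects())[:4]:
                got = entails_membership(g, ind, expr, ont)
                want = model_check_membership(g, ind, expr, ont)
                assert got == want, (ind, expr)
                agree_true += got
        assert agree_true > 10  # the comparison is not vacuously all-False


class TestClassifyAll:
    def test_empty_graph(self, ontology):
        assert classify_all(Graph(), ontology) == Graph()

    def test_demo_cascade_single_fixpoint_run(self, ontology):
        """A slope-1.2 model cascades: IncreasingModel on the model,
        ElevatedLevels on the collection, LikelyRejecter on the patient."""
        p, c, m = ex("pat"), ex("coll"), ex("model")
        g = Graph(
            frozenset(
                {
                    Triple(p, RDF_TYPE, dd.PATIENT),
                    Triple(p, dd.HAS_CREATININE_COLLECTION, c),
                    Triple(c, RDF_TYPE, dd.MEASUREMENT_COLLECTION),
                    Triple(c, dd.HAS_REGRESSION_MODEL, m),
                    Triple(m, RDF_TYPE, dd.LINEAR_REGRESSION_MODEL),
                    Triple(m, dd.SLOPE, decimal_literal("1.2")),
                }
            )
        )
        out = classify_all(g, ontology)
        assert Triple(m, RDF_TYPE, dd.INCREASING_MODEL) in out
        assert Triple(c, RDF_TYPE, dd.ELEVATED_LEVELS) in out
        assert Triple(p, RDF_TYPE, dd.LIKELY_REJECTER) in out

    def test_subclass_closure_materialized(self, ontology):
        g = Graph(frozenset({Triple(ex("c"), RDF_TYPE, dd.BLOOD_CHEMISTRY_TIME_COURSE)}))
        out = classify_all(g, ontology)
        assert Triple(ex("c"), RDF_TYPE, dd.XY_COORDINATE_DATA) in out

    def test_matches_model_checker_on_random_graphs(self):
        rng = random.Random(99)
        for _ in range(40):
            ont = random_ontology(rng)
            g = random_instance_graph(rng, n_individuals=10)
            out = classify_all(g, ont)
            want_types = model_check_types(g, ont)
            got_types = {}
            for t in out.triples:
                if t.predicate == RDF_TYPE and isinstance(t.object, IRI):
                    got_types.setdefault(t.subject, set()).add(t.object)
            for ind, classes in want_types.items():
                assert got_types.get(ind, set()) >= classes
            # and nothing extra is derived beyond asserted + oracle types
            for ind, classes in got_types.items():
                asserted = {
                    t.object
                    for t in g.match(ind, RDF_TYPE)
                    if isinstance(t.object, IRI)
                }
                assert classes <= want_types.get(ind, set()) | asserted

    def test_monotone_and_idempotent(self, ontology, noiseless_cohort):
        _, g, _ = noiseless_cohort
        once = classify_all(g, ontology)
        assert once.triples >= g.triples
        assert classify_all(once, ontology) == once

    def test_adding_triples_never_removes_entailments(self, ontology):
        rng = random.Random(5)
        g = random_instance_graph(rng)
        extra = Graph(frozenset({Triple(ex("zz"), RDF_TYPE, BASE_CLASSES[0])}))
        small = classify_all(g, ontology)
        big = classify_all(g.merge(extra), ontology)
        assert small.triples - g.triples <= big.triples
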