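import random

import pytest

from owlflow import Registry, demo_ontology, demo_services
from owlflow.rdf_core import Graph, IRI, Literal, Triple, RDF_TYPE, decimal_literal
from owlflow.ontology_core import (
    IntersectionOf,
    NamedClass,
    NumericRange,
    Ontology,
    SomeValuesFrom,
)
from owlflow.synthetic_data import CohortSpec, generate_cohort

#: the demonstrative clinical query, exactly as published
REJECTER_QUERY = """PREFIX rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
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


@pytest.fixture(scope="session")
def ontology():
    return demo_ontology()


@pytest.fixture()
def registry(ontology):
    reg = Registry(ontology=ontology)
    for s in demo_services():
        reg.register(s)
    return reg


@pytest.fixture(scope="session")
def rejecter_query():
    return REJECTER_QUERY


@pytest.fixture(scope="session")
def noiseless_cohort():
    spec = CohortSpec(n_patients=10, fraction_rejecter=0.4, noise_sd=0.0, seed=1)
    g, truth = generate_cohort(spec)
    return spec, g, truth


# ---------------------------------------------------------------------------
# random-structure generators (plain `random` for reproducibility)
# ---------------------------------------------------------------------------

EX = "http://example.org/test#"


def ex(local: str) -> IRI:
    return IRI(EX + local)


BASE_CLASSES = [ex(f"C{i}") for i in range(4)]
PROPS = [ex(f"p{i}") for i in range(3)]
XSD_DECIMAL = IRI("http://www.w3.org/2001/XMLSchema#decimal")


def random_expression(rng: random.Random, depth: int = 3):
    """A random class expression of the supported fragment, depth-bounded."""
    choices = ["named"]
    if depth > 0:
        choices += ["intersection", "some_class", "some_range"]
    kind = rng.choice(choices)
    if kind == "named":
        return NamedClass(rng.choice(BASE_CLASSES))
    if kind == "intersection":
        n = rng.randint(2, 3)
        return IntersectionOf(tuple(random_expression(rng, depth - 1) for _ in range(n)))
    if kind == "some_class":
        return SomeValuesFrom(rng.choice(PROPS), random_expression(rng, depth - 1))
    lo = rng.randint(-5, 5)
    facets = {}
    if rng.random() < 0.8:
        facets[rng.choice(["minInclusive", "minExclusive"])] = lo
    if rng.random() < 0.5:
        facets[rng.choice(["maxInclusive", "maxExclusive"])] = lo + rng.randint(1, 6)
    return SomeValuesFrom(rng.choice(PROPS), NumericRange.of(XSD_DECIMAL, **facets))


def random_ontology(rng: random.Random) -> Ontology:
    """Random acyclic ontology: a couple of subclass/subproperty axioms and
    up to two defined classes whose definitions mention only base classes."""
    subclass = set()
    for _ in range(rng.randint(0, 2)):
        a, b = rng.sample(BASE_CLASSES, 2)
        if (b, a) not in subclass:
            subclass.add((a, b))
    subprop = set()
    if rng.random() < 0.5:
        a, b = rng.sample(PROPS, 2)
        subprop.add((a, b))
    definitions = {}
    for i in range(rng.randint(0, 2)):
        definitions[ex(f"D{i}")] = random_expression(rng, depth=2)
    try:
        return Ontology(definitions, subclass, subprop)
    except Exception:
        return Ontology({}, subclass, subprop)


def random_instance_graph(rng: random.Random, n_individuals: int = 12) -> Graph:
    inds = [ex(f"i{k}") for k in range(rng.randint(1, n_individuals))]
    triples = set()
    for ind in inds:
        for _ in range(rng.randint(0, 2)):
            triples.add(Triple(ind, RDF_TYPE, rng.choice(BASE_CLASSES)))
        for _ in range(rng.randint(0, 3)):
            p = rng.choice(PROPS)
            if rng.random() < 0.5:
                obj = rng.choice(inds)
            else:
                obj = decimal_literal(rng.randint(-6, 8))
            triples.add(Triple(ind, p, obj))
    return Graph(frozenset(triples))
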