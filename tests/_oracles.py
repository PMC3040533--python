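"""Independent brute-force oracles used to cross-check the implementation.

Each oracle deliberately uses a different algorithm from the code under
test: the join oracle is a nested-loop enumeration, the model checker is a
set-based extension fixpoint (vs the engine's per-individual backward
chaining), and the regression oracle is numpy's polyfit.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from owlflow.rdf_core import Graph, IRI, Literal, RDF_TYPE, Term, Triple
from owlflow.ontology_core import (
    ClassExpression,
    HasValue,
    IntersectionOf,
    MembershipReq,
    NamedClass,
    NumericRange,
    Ontology,
    OWL_THING,
    PropertyReq,
    SomeValuesFrom,
    decompose,
    individuals,
)


# ---------------------------------------------------------------------------
# nested-loop join oracle for basic graph patterns
# ---------------------------------------------------------------------------


def join_oracle(g: Graph, patterns: List[Tuple]) -> List[Dict[str, Term]]:
    """Evaluate a BGP by brute force: try every assignment of each pattern
    to every triple, nested-loop joining on shared variables.

    Patterns are (s, p, o) tuples where strings starting with '?' are
    variables and other entries are IRI/Literal terms.
    """

    def unify(pattern, triple: Triple, binding: Dict[str, Term]) -> Optional[Dict[str, Term]]:
        out = dict(binding)
        for pat_term, val in zip(pattern, (triple.subject, triple.predicate, triple.object)):
            if isinstance(pat_term, str) and pat_term.startswith("?"):
                if pat_term in out:
                    if out[pat_term] != val:
                        return None
                else:
                    out[pat_term] = val
            elif pat_term != val:
                return None
        return out

    solutions: List[Dict[str, Term]] = [{}]
    for pattern in patterns:
        next_solutions = []
        for binding in solutions:
            for triple in g.triples:
                unified = unify(pattern, triple, binding)
                if unified is not None:
                    next_solutions.append(unified)
        solutions = next_solutions
    return [{k.lstrip("?"): v for k, v in s.items()} for s in solutions]


# ---------------------------------------------------------------------------
# set-based model checker (extension fixpoint)
# ---------------------------------------------------------------------------


def _extension(
    expr,
    g: Graph,
    ont: Ontology,
    types: Dict[IRI, Set[IRI]],
) -> Set[IRI]:
    """All individuals satisfying ``expr`` under the current type map."""
    inds = individuals(g)
    if isinstance(expr, NamedClass):
        if expr.iri == OWL_THING:
            return set(inds)
        return {i for i in inds if expr.iri in types.get(i, set())}
    if isinstance(expr, IntersectionOf):
        out = set(inds)
        for m in expr.members:
            out &= _extension(m, g, ont, types)
        return out
    if isinstance(expr, SomeValuesFrom):
        preds = ont.subproperties(expr.property)
        filler = expr.filler
        out = set()
        if isinstance(filler, NumericRange):
            for t in g.triples:
                if t.predicate in preds and isinstance(t.object, Literal):
                    d = t.object.as_decimal()
                    if d is not None and filler.contains(d):
                        out.add(t.subject)
        else:
            filler_ext = _extension(filler, g, ont, types)
            for t in g.triples:
                if t.predicate in preds and isinstance(t.object, IRI) and t.object in filler_ext:
                    out.add(t.subject)
        return out
    if isinstance(expr, HasValue):
        preds = ont.subproperties(expr.property)
        return {
            t.subject for t in g.triples if t.predicate in preds and t.object == expr.value
        }
    raise TypeError(f"unexpected expression {expr!r}")


def model_check_types(g: Graph, ont: Ontology) -> Dict[IRI, Set[IRI]]:
    """Final (individual → named classes) map: asserted types closed under
    the subclass hierarchy plus defined-class extensions, iterated to
    fixpoint by set operations."""
    types: Dict[IRI, Set[IRI]] = {}
    for t in g.triples:
        if t.predicate == RDF_TYPE and isinstance(t.object, IRI):
            for sup in ont.superclasses(t.object):
                types.setdefault(t.subject, set()).add(sup)
    while True:
        changed = False
        for c, defn in ont.class_definitions.items():
            for ind in _extension(defn, g, ont, types):
                for sup in ont.superclasses(c):
                    if sup not in types.setdefault(ind, set()):
                        types[ind].add(sup)
                        changed = True
        if not changed:
            return types


def model_check_membership(g: Graph, ind: IRI, expr, ont: Ontology) -> bool:
    types = model_check_types(g, ont)
    return ind in _extension(ont.resolve(expr), g, ont, types)


# ---------------------------------------------------------------------------
# regression oracle
# ---------------------------------------------------------------------------


def polyfit_line(points) -> Tuple[float, float]:
    xs = np.array([float(x) for x, _ in points])
    ys = np.array([float(y) for _, y in points])
    slope, intercept = np.polyfit(xs, ys, 1)
    return float(slope), float(intercept)


# ---------------------------------------------------------------------------
# full-materialization oracle for the engine
# ---------------------------------------------------------------------------


def fully_materialize(g: Graph, services, ont: Ontology, max_rounds: int = 5) -> Graph:
    """Invoke every service on every eligible subject, classify, and repeat
    to fixpoint — the ground-truth final graph an ideal engine would build."""
    from owlflow.ontology_core import classify_all, entails_membership
    from owlflow.service_model import invoke

    current = classify_all(g, ont)
    for _ in range(max_rounds):
        before = len(current)
        for s in services:
            input_expr = ont.resolve(s.input_class)
            eligible = sorted(
                i for i in individuals(current) if entails_membership(current, i, input_expr, ont)
            )
            record = invoke(s, current, eligible, ont)
            current = current.merge(record.added_triples)
        current = classify_all(current, ont)
        if len(current) == before:
            break
    return current
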