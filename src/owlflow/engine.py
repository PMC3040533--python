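"""Execute query plans over a transient materialized graph.

The engine runs a plan's steps in linearized order against a working copy
of the input graph — the *transient database*.  Service outputs are merged
as they arrive (RDF merge is set union, and the supported fragment is
monotone, so order of merging never invalidates anything).  Reasoning
steps materialize entailed ``rdf:type`` triples.  After a full pass the
engine re-plans: a service's output may have made another pattern
plannable (service chains), so bounded re-planning approximates a fixpoint
without risking non-termination.  The final graph answers the original
query with plain SPARQL evaluation, then is discarded.

Every triple added along the way is attributed, exactly once, to the step
that added it — the execution trace doubles as a provenance record
(which service or reasoning round produced each assertion), and replaying
the trace's deltas over the initial graph reproduces the final graph
exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple, Union

from .rdf_core import BindingsTable, Graph, IRI, evaluate_sparql
from .ontology_core import Ontology, classify_all, entails_membership, individuals
from .planner import (
    QueryPlan,
    ReasonStep,
    ServiceStep,
    Workflow,
    plan_for_query,
)
from .registry import Registry
from .service_model import InvocationRecord, invoke

logger = logging.getLogger(__name__)

__all__ = ["StepTrace", "RoundTrace", "ExecutionTrace", "execute", "answer", "explain"]


@dataclass
class StepTrace:
    """One executed step: the triples it newly added (its provenance delta)."""

    label: str
    added: Graph
    record: Optional[InvocationRecord] = None
    note: str = ""


@dataclass
class RoundTrace:
    steps: List[StepTrace] = field(default_factory=list)
    graph_size_after: int = 0


@dataclass
class ExecutionTrace:
    initial_size: int = 0
    rounds: List[RoundTrace] = field(default_factory=list)
    warnings: List[str] = field(default_factory=list)
    final_graph_size: int = 0

    @property
    def total_added(self) -> int:
        return sum(len(s.added) for r in self.rounds for s in r.steps)

    def deltas(self) -> List[Tuple[str, Graph]]:
        return [(s.label, s.added) for r in self.rounds for s in r.steps]

    def replay(self, initial: Graph) -> Graph:
        """Re-merge every delta into the initial graph; by construction this
        reproduces the final graph exactly."""
        g = initial
        for _, delta in self.deltas():
            g = g.merge(delta)
        return g


def _service_targets(
    step: ServiceStep, g: Graph, r: Registry, ont: Ontology
) -> List[IRI]:
    svc = r.get(step.service)
    if step.fixed_subjects:
        cands = set(step.fixed_subjects)
    elif step.selector is not None:
        cands = {
            i
            for i in individuals(g)
            if entails_membership(g, i, step.selector, ont)
        }
    else:
        input_expr = ont.resolve(svc.input_class)
        cands = {
            i for i in individuals(g) if entails_membership(g, i, input_expr, ont)
        }
    # only subjects still lacking the produced predicate (merge semantics
    # make this an optimization, not a correctness choice)
    preds = ont.subproperties(step.produces)
    return sorted(
        c
        for c in cands
        if not any(t.predicate in preds for t in g.by_subject().get(c, []))
    )


def _run_workflow(
    wf: Workflow, g: Graph, r: Registry, ont: Ontology
) -> Tuple[Graph, RoundTrace]:
    current = g
    round_trace = RoundTrace()
    for step in wf.linearize():
        if isinstance(step, ReasonStep):
            classified = classify_all(current, ont)
            delta = classified.difference(current)
            current = classified
            round_trace.steps.append(StepTrace("reason", delta))
            continue
        svc = r.get(step.service)
        if svc is None or svc.implementation is None:
            note = f"service {step.service.value} unavailable; step skipped"
            logger.warning(note)
            round_trace.steps.append(StepTrace(step.label, Graph(), note=note))
            continue
        targets = _service_targets(step, current, r, ont)
        try:
            record = invoke(svc, current, targets, ont)
        except Exception as exc:  # defensive: a broken service never kills the run
            note = f"service {step.service.value} failed: {exc}"
            logger.warning(note)
            round_trace.steps.append(StepTrace(step.label, Graph(), note=note))
            continue
        delta = record.added_triples.difference(current)
        current = current.merge(record.added_triples)
        note = ""
        if record.errors:
            note = "; ".join(f"{s.value}: {m}" for s, m in record.errors)
        round_trace.steps.append(StepTrace(step.label, delta, record=record, note=note))
    round_trace.graph_size_after = len(current)
    return current, round_trace


def execute(
    plan: Union[QueryPlan, Workflow],
    g: Graph,
    r: Registry,
    ont: Ontology,
    max_rounds: int = 3,
) -> Tuple[Graph, ExecutionTrace]:
    """Run a plan to (bounded) fixpoint.

    Each round runs every step in linearized order, merging service outputs
    immediately.  If the round added triples, the plan is rebuilt against
    the enriched graph (a service's output may enable another service's
    input) and executed again, up to ``max_rounds`` rounds.  A round that
    adds nothing ends execution, so re-running on an already-final graph is
    a no-op.
    """
    trace = ExecutionTrace(initial_size=len(g))
    current = g
    current_plan = plan
    for round_idx in range(max_rounds):
        wf = current_plan.workflow if isinstance(current_plan, QueryPlan) else current_plan
        for entry in wf.unresolved():
            msg = f"unresolved requirement: {entry.render()}"
            if msg not in trace.warnings:
                trace.warnings.append(msg)
                logger.warning(msg)
        size_before = len(current)
        current, round_trace = _run_workflow(wf, current, r, ont)
        trace.rounds.append(round_trace)
        if len(current) == size_before:
            break
        if isinstance(current_plan, QueryPlan) and round_idx < max_rounds - 1:
            current_plan = plan_for_query(current_plan.query, r, ont, current)
    else:
        if trace.rounds and len(trace.rounds[-1].steps) and trace.rounds[-1].graph_size_after > trace.initial_size:
            trace.warnings.append(
                f"stopped after {max_rounds} rounds with progress still occurring"
            )
    trace.final_graph_size = len(current)
    return current, trace


def answer(
    q: str,
    g: Graph,
    r: Registry,
    ont: Ontology,
    max_rounds: int = 3,
) -> Tuple[BindingsTable, ExecutionTrace]:
    """Answer a SPARQL SELECT query with service materialization.

    Plans the query, executes the workflow over a transient copy of the
    graph, and evaluates the original query over the final materialized
    graph.  Unresolved requirements surface as trace warnings (affected
    patterns may then bind nothing — never silently)."""
    plan = plan_for_query(q, r, ont, g)
    final, trace = execute(plan, g, r, ont, max_rounds=max_rounds)
    bindings = evaluate_sparql(final, q)
    return bindings, trace


def trace_to_dict(trace: ExecutionTrace) -> dict:
    """JSON-friendly rendering of a trace (step deltas as Turtle lines)."""
    from .rdf_core import save_graph

    return {
        "initial_size": trace.initial_size,
        "final_graph_size": trace.final_graph_size,
        "warnings": list(trace.warnings),
        "rounds": [
            {
                "graph_size_after": rnd.graph_size_after,
                "steps": [
                    {
                        "label": s.label,
                        "note": s.note,
                        "added": save_graph(s.added, "turtle").splitlines(),
                    }
                    for s in rnd.steps
                ],
            }
            for rnd in trace.rounds
        ],
    }


def explain_dict(d: dict) -> str:
    """Render a serialized trace (see :func:`trace_to_dict`) as the same
    provenance report :func:`explain` produces."""
    lines: List[str] = []
    for i, rnd in enumerate(d.get("rounds", []), start=1):
        for step in rnd["steps"]:
            if not step["added"] and not step.get("note"):
                continue
            lines.append(f"round {i} / {step['label']}: +{len(step['added'])} triples")
            if step.get("note"):
                lines.append(f"  note: {step['note']}")
            for t in step["added"]:
                lines.append(f"  {t}")
    for w in d.get("warnings", []):
        lines.append(f"warning: {w}")
    return "\n".join(lines)


def explain(trace: ExecutionTrace) -> str:
    """Per-triple provenance: which service or reasoning round added each
    new triple.  Every added triple is attributed exactly once (step deltas
    are disjoint by construction)."""
    lines: List[str] = []
    for i, rnd in enumerate(trace.rounds, start=1):
        for step in rnd.steps:
            if not step.added and not step.note:
                continue
            lines.append(f"round {i} / {step.label}: +{len(step.added)} triples")
            if step.note:
                lines.append(f"  note: {step.note}")
            for t in step.added.sorted_triples():
                obj = (
                    f"<{t.object.value}>"
                    if isinstance(t.object, IRI)
                    else f'"{t.object.lexical_form}"'
                )
                lines.append(f"  <{t.subject.value}> <{t.predicate.value}> {obj}")
    for w in trace.warnings:
        lines.append(f"warning: {w}")
    return "\n".join(lines)
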