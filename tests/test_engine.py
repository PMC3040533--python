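"""Plan execution: materialization, provenance traces, end-to-end answers."""

import random

import pytest

import owlflow.demo_domain as dd
from owlflow.engine import answer, execute, explain
from owlflow.planner import plan_for_query
from owlflow.rdf_core import Graph, IRI, RDF_TYPE, Triple, decimal_literal, evaluate_sparql
from owlflow.synthetic_data import CohortSpec, generate_cohort

from _oracles import fully_materialize


def three_patient_fixture():
    """Three hand-built patients with creatinine slopes +, 0, −."""
    triples = set()
    series = {"up": [(0, 1.0), (7, 1.5), (14, 2.0)],
              "flat": [(0, 1.0), (7, 1.0), (14, 1.0)],
              "down": [(0, 2.0), (7, 1.5), (14, 1.0)]}
    bun = [(0, 15.0), (7, 16.0), (14, 14.0)]
    for name, pts in series.items():
        pat = IRI(f"http://e/pat-{name}")
        triples.add(Triple(pat, RDF_TYPE, dd.PATIENT))
        for analyte, link, pts_a in [
            ("creat", dd.HAS_CREATININE_COLLECTION, pts),
            ("bun", dd.HAS_BUN_COLLECTION, bun),
        ]:
            coll = IRI(f"{pat.value}/{analyte}")
            triples |= {
                Triple(pat, link, coll),
                Triple(coll, RDF_TYPE, dd.MEASUREMENT_COLLECTION),
                Triple(coll, RDF_TYPE, dd.BLOOD_CHEMISTRY_TIME_COURSE),
            }
            for i, (x, y) in enumerate(pts_a):
                m = IRI(f"{coll.value}/m{i}")
                triples |= {
                    Triple(coll, dd.HAS_MEASUREMENT, m),
                    Triple(m, RDF_TYPE, dd.MEASUREMENT),
                    Triple(m, dd.X_OFFSET, decimal_literal(x)),
                    Triple(m, dd.Y_VALUE, decimal_literal(y)),
                }
    return Graph(frozenset(triples))


class TestExecute:
    def test_reason_only_plan_on_classified_data_is_single_round(
        self, registry, ontology, rejecter_query
    ):
        g = three_patient_fixture()
        final_oracle = fully_materialize(g, dd.demo_services(), ontology)
        plan = plan_for_query(rejecter_query, registry, ontology, final_oracle)
        final, trace = execute(plan, final_oracle, registry, ontology)
        assert final == final_oracle
        assert len(trace.rounds) == 1
        assert trace.total_added == 0

    def test_three_patient_slopes_classify_only_the_riser(
        self, registry, ontology, rejecter_query
    ):
        g = three_patient_fixture()
        plan = plan_for_query(rejecter_query, registry, ontology, g)
        final, trace = execute(plan, g, registry, ontology)
        rejecters = {
            t.subject for t in final.match(None, RDF_TYPE, dd.LIKELY_REJECTER)
        }
        assert rejecters == {IRI("http://e/pat-up")}
        # regression models were fitted for all six collections
        assert len(list(final.match(None, dd.HAS_REGRESSION_MODEL))) == 6
        # latest values only for the rejecter (scoped invocation)
        assert {t.subject for t in final.match(None, dd.LATEST_CREATININE)} == rejecters
        assert {t.subject for t in final.match(None, dd.LATEST_BUN)} == rejecters

    def test_reexecution_on_final_graph_adds_nothing(self, registry, ontology, rejecter_query):
        g = three_patient_fixture()
        plan = plan_for_query(rejecter_query, registry, ontology, g)
        final, _ = execute(plan, g, registry, ontology)
        plan2 = plan_for_query(rejecter_query, registry, ontology, final)
        final2, trace2 = execute(plan2, final, registry, ontology)
        assert final2 == final
        assert trace2.total_added == 0

    def test_trace_replay_reproduces_final_graph_exactly(
        self, registry, ontology, rejecter_query
    ):
        g = three_patient_fixture()
        plan = plan_for_query(rejecter_query, registry, ontology, g)
        final, trace = execute(plan, g, registry, ontology)
        assert trace.replay(g) == final
        assert trace.initial_size == len(g)
        assert trace.final_graph_size == len(final)

    def test_graph_size_nondecreasing_across_rounds(self, registry, ontology, rejecter_query):
        g = three_patient_fixture()
        plan = plan_for_query(rejecter_query, registry, ontology, g)
        _, trace = execute(plan, g, registry, ontology)
        sizes = [trace.initial_size] + [r.graph_size_after for r in trace.rounds]
        assert sizes == sorted(sizes)

    def test_broken_service_degrades_gracefully(self, registry, ontology, rejecter_query):
        """A service whose implementation raises is recorded and skipped;
        the rest of the query still runs."""
        from owlflow.service_model import ServiceDescription

        def boom(g, subjects):
            raise RuntimeError("backend down")

        broken = ServiceDescription(
            iri=dd.regression_service().iri,
            name=dd.regression_service().name,
            input_class=dd.regression_service().input_class,
            output_class=dd.regression_service().output_class,
            implementation=boom,
        )
        registry.deregister(broken.iri)
        registry.register(broken)
        g = three_patient_fixture()
        bindings, trace = answer(rejecter_query, g, registry, ontology)
        assert len(bindings) == 0  # no regression models → no rejecters
        errors = [
            s.note
            for r in trace.rounds
            for s in r.steps
            if s.record is not None and s.record.errors
        ]
        assert errors and "backend down" in errors[0]


class TestAnswer:
    def test_query_over_empty_graph(self, registry, ontology, rejecter_query):
        bindings, _ = answer(rejecter_query, Graph(), registry, ontology)
        assert len(bindings) == 0

    def test_published_query_returns_ground_truth_rejecters(
        self, registry, ontology, rejecter_query, noiseless_cohort
    ):
        _, g, truth = noiseless_cohort
        bindings, _ = answer(rejecter_query, g, registry, ontology)
        assert {row["patient"] for row in bindings} == truth.oracle_rejecters()

    def test_answer_equals_evaluation_over_fully_materialized_oracle_graph(
        self, registry, ontology, rejecter_query
    ):
        """End-to-end equivalence on randomized noisy cohorts: the engine's
        answer equals plain SPARQL over the brute-force materialization."""
        for seed in range(5):
            spec = CohortSpec(
                n_patients=8, fraction_rejecter=0.5, noise_sd=0.1, seed=seed
            )
            g, truth = generate_cohort(spec)
            got, _ = answer(rejecter_query, g, registry, ontology)
            oracle_graph = fully_materialize(g, dd.demo_services(), ontology)
            want = evaluate_sparql(oracle_graph, rejecter_query)
            assert got == want
            assert {row["patient"] for row in got} == truth.oracle_rejecters()

    def test_unresolved_requirement_surfaces_as_warning(
        self, registry, ontology, rejecter_query
    ):
        registry.deregister(dd.regression_service().iri)
        g = three_patient_fixture()
        bindings, trace = answer(rejecter_query, g, registry, ontology)
        assert len(bindings) == 0
        assert any("unresolved" in w for w in trace.warnings)
        assert any("hasRegressionModel" in w for w in trace.warnings)


class TestExplain:
    def test_empty_trace_renders_empty_report(self):
        from owlflow.engine import ExecutionTrace

        assert explain(ExecutionTrace()) == ""

    def test_attribution_names_service_and_reasoner(self, registry, ontology, rejecter_query):
        g = three_patient_fixture()
        plan = plan_for_query(rejecter_query, registry, ontology, g)
        _, trace = execute(plan, g, registry, ontology)
        report = explain(trace)
        assert "linear-regression" in report
        assert "reason" in report
        # the regression triples are attributed to the regression service
        for line_group in report.split("round "):
            lines = line_group.splitlines()
            if lines and "linear-regression" in lines[0]:
                assert "hasRegressionModel" in line_group

    def test_attribution_is_an_exact_partition_of_added_triples(
        self, registry, ontology, rejecter_query
    ):
        g = three_patient_fixture()
        plan = plan_for_query(rejecter_query, registry, ontology, g)
        final, trace = execute(plan, g, registry, ontology)
        deltas = [delta for _, delta in trace.deltas()]
        union = Graph()
        total = 0
        for d in deltas:
            assert len(union.triples & d.triples) == 0  # pairwise disjoint
            union = union.merge(d)
            total += len(d)
        assert total == trace.total_added
        assert union == final.difference(g)
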