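"""Competency-question suite: executability, fixture answers, mock joins,
conservation against the object model, and SIRO-only audits."""

import pytest
from rdflib import Graph

from smartprotocols.authoring import SynthConfig, synthesize_protocol
from smartprotocols.errors import MissingMockError
from smartprotocols.queries import (
    MOCK_NAMES,
    get_query,
    load_all_mocks,
    load_competency_suite,
    load_mock_graph,
    run_query,
    run_siro_only_audit,
)
from smartprotocols.rdf import to_rdf
from smartprotocols.siro import export_siro_rdf, extract_siro


@pytest.fixture(scope="module")
def fixture_graph(fixture_protocol, registry):
    return to_rdf(fixture_protocol, registry)


@pytest.fixture(scope="module")
def mocks():
    return load_all_mocks()


class TestSuite:
    def test_ids_unique_and_expected_questions_present(self):
        suite = load_competency_suite()
        ids = [q.id for q in suite]
        assert len(ids) == len(set(ids))
        assert {"protocols-by-sample", "reagents-with-manufacturer",
                "caution-steps", "protocols-by-author",
                "protocols-by-author-and-sample", "common-reagents",
                "protocols-by-sample-order", "reagent-vendors",
                "diseases-by-reagent"} <= set(ids)

    def test_caution_question_is_worded_as_published(self):
        q = get_query("caution-steps")
        assert "CAUTIONS as alert messages" in q.description

    def test_every_query_runs_on_empty_graph(self, mocks):
        for q in load_competency_suite():
            assert run_query(Graph(), q, mocks) == []

    def test_every_query_runs_on_fixture_graph(self, fixture_graph, mocks):
        for q in load_competency_suite():
            run_query(fixture_graph, q, mocks)  # must not raise

    def test_missing_mock_raises(self, fixture_graph):
        q = get_query("protocols-by-sample-order")
        with pytest.raises(MissingMockError):
            run_query(fixture_graph, q, mocks=[])

    def test_unknown_mock_name(self):
        with pytest.raises(MissingMockError):
            load_mock_graph("dbpedia")

    def test_all_mocks_load(self):
        for mg in load_all_mocks():
            assert mg.name in MOCK_NAMES
            assert len(mg.triples) > 0


class TestAnswers:
    def test_protocols_by_tumor_tissue_sample(self, fixture_graph):
        rows = run_query(fixture_graph, get_query("protocols-by-sample"),
                         params={"sample_name": "tumor tissue"})
        assert len(rows) == 1
        assert rows[0][1] == \
            "Extraction of total RNA from fresh/frozen tissue (FT)"

    def test_absent_sample_returns_nothing(self, fixture_graph):
        rows = run_query(fixture_graph, get_query("protocols-by-sample"),
                         params={"sample_name": "moon rock"})
        assert rows == []

    def test_reagents_with_manufacturer(self, fixture_graph):
        rows = run_query(fixture_graph, get_query("reagents-with-manufacturer"),
                         params={"protocol_id": "rna-extraction-ft"})
        assert dict(rows) == {
            "TRIzol": "Invitrogen", "Chloroform": "Sigma-Aldrich",
            "Ethyl alcohol": "Sigma-Aldrich",
            "Isopropyl alcohol": "Sigma-Aldrich"}

    def test_protocols_by_author(self, fixture_graph):
        rows = run_query(fixture_graph, get_query("protocols-by-author"),
                         params={"author_name": "Yvonne Hey"})
        assert len(rows) == 1

    def test_author_and_sample_subset_of_author_only(self, fixture_graph):
        both = run_query(fixture_graph,
                         get_query("protocols-by-author-and-sample"),
                         params={"author_name": "Yvonne Hey",
                                 "sample_name": "tumor tissue"})
        author_only = run_query(fixture_graph, get_query("protocols-by-author"),
                                params={"author_name": "Yvonne Hey"})
        assert set(both) <= set(author_only)
        assert len(both) == 1

    def test_diseases_by_reagent_via_hazards_mock(self, fixture_graph, mocks):
        rows = run_query(fixture_graph, get_query("diseases-by-reagent"), mocks,
                         params={"protocol_id": "rna-extraction-ft"})
        assert ("Chloroform", "toxic liver disease") in rows

    def test_reagent_vendors_mock_join(self, fixture_graph, mocks):
        rows = run_query(fixture_graph, get_query("reagent-vendors"), mocks)
        assert any(r[0] == "TRIzol" and r[1] == "Invitrogen" for r in rows)

    def test_rodent_order_query_via_taxa_mock(self, registry, mocks):
        # a synthetic protocol whose specimen organism is Mus musculus
        p = synthesize_protocol(SynthConfig(seed=8,
                                            material_pool_sizes={"specimen": 6}))
        organisms = {s.organism for s in p.document.specimens}
        assert "Mus musculus" in organisms
        g = to_rdf(p, registry)
        rows = run_query(g, get_query("protocols-by-sample-order"), mocks,
                         params={"order_name": "Rodentia"})
        assert rows and all(r[2] in ("Mus musculus", "Rattus norvegicus")
                            for r in rows)

    def test_common_reagents_equal_planted_intersection(self, registry):
        a = synthesize_protocol(SynthConfig(seed=21, material_pool_sizes={
            "reagent": 7}))
        b = synthesize_protocol(SynthConfig(seed=33, material_pool_sizes={
            "reagent": 7}))
        # oracle: set intersection over the generated declarations
        planted = ({r.name for r in a.document.reagents} &
                   {r.name for r in b.document.reagents})
        assert planted  # the pools guarantee overlap at these sizes
        dataset = Graph()
        for t in to_rdf(a, registry):
            dataset.add(t)
        for t in to_rdf(b, registry):
            dataset.add(t)
        rows = run_query(dataset, get_query("common-reagents"),
                         params={"protocol_a": a.id, "protocol_b": b.id})
        assert {r[0] for r in rows} == planted

    def test_caution_rows_equal_object_model_count(self, registry):
        p = synthesize_protocol(SynthConfig(seed=13, p_alert=0.8))
        expected = sum(
            any(a.kind == "caution" for a in s.alerts)
            for proc in p.workflow.procedures for s in proc.subprocedures)
        rows = run_query(to_rdf(p, registry), get_query("caution-steps"),
                         params={"protocol_id": p.id})
        assert len(rows) == expected

    def test_rows_invariant_under_triple_permutation(self, fixture_graph):
        forward, backward = Graph(), Graph()
        triples = sorted(fixture_graph)
        for t in triples:
            forward.add(t)
        for t in reversed(triples):
            backward.add(t)
        q = get_query("protocols-by-sample")
        params = {"sample_name": "tumor tissue"}
        assert run_query(forward, q, params=params) == \
            run_query(backward, q, params=params)


class TestSIROAudit:
    def test_fixture_siro_export_answers_and_suppresses(self, fixture_protocol,
                                                        registry):
        g = export_siro_rdf(extract_siro(fixture_protocol), registry)
        rows = run_query(g, get_query("protocols-by-sample"),
                         params={"sample_name": "tumor tissue"})
        assert len(rows) == 1
        assert run_query(g, get_query("caution-steps"),
                         params={"protocol_id": fixture_protocol.id}) == []
        report = run_siro_only_audit(g, registry)
        assert report.is_privacy_preserving()
        assert report.answerable["protocols-by-sample"] >= 1

    @pytest.mark.parametrize("seed", range(20))
    def test_synthetic_siro_only_protocols_never_expose_steps(self, seed,
                                                              registry):
        p = synthesize_protocol(SynthConfig(seed=seed, visibility="siro_only"))
        g = export_siro_rdf(extract_siro(p), registry)
        report = run_siro_only_audit(g, registry)
        assert report.is_privacy_preserving()
        assert all(n == 0 for n in report.suppressed.values())
        assert report.answerable["protocols-by-sample"] >= 1
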