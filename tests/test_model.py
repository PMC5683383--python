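"""Workflow-layer structural semantics: ordering, IO chaining, validation."""

import itertools
import random

import pytest
from hypothesis import given, strategies as st

from smartprotocols import model as m
from smartprotocols.errors import AmbiguityWarning, CycleError, EmptyStepsError
from smartprotocols.model import (
    linearize_subprocedures,
    resolve_io_chain,
    validate_structure,
    wrap_flat_steps,
)


def make_steps(n, links=None):
    """n steps named s1..sn; links maps step index -> predecessor index."""
    steps = [m.LabSubprocedure(id=f"s{i + 1}", text=f"step {i + 1}")
             for i in range(n)]
    for i, pred in (links or {}).items():
        steps[i].preceded_by = steps[pred].id
    return steps


def brute_force_orders(steps):
    """All permutations consistent with every preceded_by link (oracle)."""
    orders = []
    for perm in itertools.permutations(steps):
        pos = {s.id: i for i, s in enumerate(perm)}
        if all(s.preceded_by is None or pos[s.preceded_by] < pos[s.id]
               for s in perm):
            orders.append([s.id for s in perm])
    return orders


class TestLinearize:
    def test_full_chain_follows_links(self):
        # the three sample-preparation steps chained 1.1 -> 1.2 -> 1.3
        steps = [
            m.LabSubprocedure(id="lab subprocedure 1.2", text="thaw and weigh",
                              preceded_by="lab subprocedure 1.1"),
            m.LabSubprocedure(id="lab subprocedure 1.3", text="homogenize",
                              preceded_by="lab subprocedure 1.2"),
            m.LabSubprocedure(id="lab subprocedure 1.1", text="recover tissue"),
        ]
        proc = m.LabProcedure(id="p1", subprocedures=steps)
        assert [s.id for s in linearize_subprocedures(proc)] == [
            "lab subprocedure 1.1", "lab subprocedure 1.2",
            "lab subprocedure 1.3"]

    def test_single_step_identity(self):
        proc = m.LabProcedure(id="p", subprocedures=make_steps(1))
        assert [s.id for s in linearize_subprocedures(proc)] == ["s1"]

    def test_shuffled_six_step_chain_matches_permutation_oracle(self):
        rng = random.Random(42)
        base = make_steps(6, links={i: i - 1 for i in range(1, 6)})
        shuffled = base[:]
        rng.shuffle(shuffled)
        proc = m.LabProcedure(id="p", subprocedures=shuffled)
        got = [s.id for s in linearize_subprocedures(proc)]
        oracle = brute_force_orders(shuffled)
        assert len(oracle) == 1  # a full chain admits a unique order
        assert got == oracle[0]

    @pytest.mark.parametrize("n", range(2, 8))
    def test_random_partial_orders_agree_with_oracle(self, n):
        rng = random.Random(n * 101)
        for _ in range(20):
            links = {i: rng.randrange(i) for i in range(1, n)
                     if rng.random() < 0.6}
            steps = make_steps(n, links)
            rng.shuffle(steps)
            proc = m.LabProcedure(id="p", subprocedures=steps)
            with pytest.warns((AmbiguityWarning, UserWarning)) if 0 < len(
                    links) < n - 1 else _nullcontext():
                got = [s.id for s in linearize_subprocedures(proc)]
            assert sorted(got) == sorted(s.id for s in steps)  # conservation
            assert got in brute_force_orders(steps)

    def test_cycle_raises(self):
        steps = make_steps(3, links={0: 2, 1: 0, 2: 1})
        proc = m.LabProcedure(id="p", subprocedures=steps)
        with pytest.raises(CycleError):
            linearize_subprocedures(proc)

    def test_partial_order_records_ambiguity_warning(self):
        steps = make_steps(4, links={1: 0})  # s3, s4 unconstrained
        proc = m.LabProcedure(id="p", subprocedures=steps)
        with pytest.warns(AmbiguityWarning):
            out = linearize_subprocedures(proc)
        assert [s.id for s in out] == ["s1", "s2", "s3", "s4"]

    def test_no_links_is_document_order_without_warning(self, recwarn):
        proc = m.LabProcedure(id="p", subprocedures=make_steps(5))
        out = linearize_subprocedures(proc)
        assert [s.id for s in out] == ["s1", "s2", "s3", "s4", "s5"]
        assert not [w for w in recwarn if issubclass(w.category,
                                                     AmbiguityWarning)]


class _nullcontext:
    def __enter__(self):
        return None

    def __exit__(self, *exc):
        return False


class TestResolveIOChain:
    def test_running_example_single_link(self, fixture_protocol):
        links, unmatched = resolve_io_chain(fixture_protocol)
        assert links == [m.IOLink("lab procedure 1", "homogenized tissue",
                                  "lab procedure 3")]
        assert unmatched == []

    def test_declared_specimen_input_is_not_chained(self):
        doc = m.DocumentMetadata(title="t",
                                 specimens=[m.Specimen(name="tumor tissue")])
        wf = m.Workflow(procedures=[m.LabProcedure(
            id="p1", inputs=[m.FlowItem(name="tumor tissue")],
            subprocedures=make_steps(1))])
        result = resolve_io_chain(m.Protocol(id="x", document=doc, workflow=wf))
        assert result.links == [] and result.unmatched == []

    def test_eight_procedure_chain_matches_pairwise_oracle(self):
        n = 8
        procs = []
        for i in range(n):
            procs.append(m.LabProcedure(
                id=f"p{i}",
                inputs=[m.FlowItem(name=f"mat{i}")] if i else [],
                outputs=[m.FlowItem(name=f"mat{i + 1}")],
                subprocedures=make_steps(1)))
        wf = m.Workflow(procedures=procs)
        links, unmatched = resolve_io_chain(wf)
        # oracle: brute-force over all ordered pairs testing name equality
        expected = set()
        for ci, c in enumerate(procs):
            for item in c.inputs:
                for pi in range(ci - 1, -1, -1):
                    if any(o.name == item.name for o in procs[pi].outputs):
                        expected.add((procs[pi].id, item.name, c.id))
                        break
        assert set(links) == expected and len(links) == n - 1
        assert unmatched == []

    def test_consumer_never_links_to_later_producer(self):
        # the producer appears after the consumer: no link, one warning
        wf = m.Workflow(procedures=[
            m.LabProcedure(id="a", inputs=[m.FlowItem(name="lysate")],
                           subprocedures=make_steps(1)),
            m.LabProcedure(id="b", outputs=[m.FlowItem(name="lysate")],
                           subprocedures=make_steps(1)),
        ])
        links, unmatched = resolve_io_chain(wf)
        assert links == []
        assert unmatched == [("a", "lysate")]

    def test_name_matching_is_case_and_whitespace_insensitive(self):
        wf = m.Workflow(procedures=[
            m.LabProcedure(id="a", outputs=[m.FlowItem(name="Homogenized  Tissue")],
                           subprocedures=make_steps(1)),
            m.LabProcedure(id="b", inputs=[m.FlowItem(name="homogenized tissue")],
                           subprocedures=make_steps(1)),
        ])
        links, _ = resolve_io_chain(wf)
        assert links == [m.IOLink("a", "homogenized tissue", "b")]


def dfs_has_cycle(units):
    """Independent cycle oracle: walk each predecessor chain to exhaustion."""
    index = {u.id: u for u in units}
    for start in units:
        seen = {start.id}
        cur = index.get(start.preceded_by) if start.preceded_by else None
        while cur is not None:
            if cur.id in seen:
                return True
            seen.add(cur.id)
            cur = index.get(cur.preceded_by) if cur.preceded_by else None
    return False


class TestValidateStructure:
    def test_running_example_has_no_errors(self, fixture_protocol):
        report = validate_structure(fixture_protocol)
        assert report.errors == []
        assert report.is_valid()

    def test_empty_workflow_reported(self):
        p = m.Protocol(id="x", document=m.DocumentMetadata(title="t"),
                       workflow=m.Workflow())
        report = validate_structure(p)
        assert [i.code for i in report.errors] == ["workflow.empty"]

    def test_cycle_detected_exactly_once_and_agrees_with_dfs_oracle(self):
        steps = make_steps(3, links={0: 1, 1: 2, 2: 0})
        assert dfs_has_cycle(steps)  # oracle agrees there is a cycle
        p = m.Protocol(
            id="x", document=m.DocumentMetadata(title="t"),
            workflow=m.Workflow(procedures=[
                m.LabProcedure(id="p1", subprocedures=steps)]))
        codes = [i.code for i in validate_structure(p).errors]
        assert codes.count("order.cycle") == 1

    def test_duplicate_id_mutation_introduces_error(self, fixture_protocol):
        import copy

        p = copy.deepcopy(fixture_protocol)
        p.workflow.procedures[1].id = p.workflow.procedures[0].id
        report = validate_structure(p)
        assert any(i.code == "procedure.id.duplicate" for i in report.errors)

    def test_catalog_number_without_manufacturer_is_error(self):
        doc = m.DocumentMetadata(
            title="t", reagents=[m.Reagent(name="TRIzol", catalog_number="15596026")])
        p = m.Protocol(id="x", document=doc, workflow=m.Workflow(
            procedures=[m.LabProcedure(id="p1", subprocedures=make_steps(1))]))
        codes = [i.code for i in validate_structure(p).errors]
        assert "material.catalog_without_manufacturer" in codes

    def test_dangling_precedence_reported(self):
        p = m.Protocol(
            id="x", document=m.DocumentMetadata(title="t"),
            workflow=m.Workflow(procedures=[m.LabProcedure(
                id="p1",
                subprocedures=[m.LabSubprocedure(id="s1", text="do",
                                                 preceded_by="ghost")])]))
        assert any(i.code == "order.dangling"
                   for i in validate_structure(p).errors)

    def test_validation_never_mutates(self, fixture_protocol):
        import copy

        before = copy.deepcopy(fixture_protocol)
        validate_structure(fixture_protocol)
        assert fixture_protocol == before


class TestWrapFlatSteps:
    def test_five_flat_steps_become_one_container(self):
        steps = make_steps(5)
        proc = wrap_flat_steps(steps)
        assert proc.kind == "container"
        assert len(proc.subprocedures) == 5
        assert proc.label  # auto-generated

    def test_empty_list_raises(self):
        with pytest.raises(EmptyStepsError):
            wrap_flat_steps([])

    @given(st.integers(min_value=1, max_value=10))
    def test_container_preserves_order_and_count(self, n):
        steps = make_steps(n)
        proc = wrap_flat_steps(steps)
        assert [s.id for s in linearize_subprocedures(proc)] == \
               [s.id for s in steps]
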