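"""Process graphs: BPMN parsing, validation, nominal path durations."""

import itertools

import pytest

from wardflow.errors import MalformedProcess, UnresolvedBranch
from wardflow.fixtures import build_random_process
from wardflow.hospital import Area, HospitalState, TransitMatrix
from wardflow.process import (
    Edge,
    ProcessGraph,
    ResourceDemand,
    branch_nominal_sum,
    nominal_path_duration,
    parse_bpmn,
    to_bpmn,
    validate_process,
)

from conftest import linear_bpmn, one_area_hospital


PARALLEL_DOC = """
<definitions xmlns="http://www.omg.org/spec/BPMN/20100524/MODEL">
 <process id="p">
  <startEvent id="start"/>
  <parallelGateway id="sp"/><parallelGateway id="jn"/>
  <task id="T1"/><task id="T2"/>
  <endEvent id="end"/>
  <sequenceFlow id="f1" sourceRef="start" targetRef="sp"/>
  <sequenceFlow id="f2" sourceRef="sp" targetRef="T1"/>
  <sequenceFlow id="f3" sourceRef="sp" targetRef="T2"/>
  <sequenceFlow id="f4" sourceRef="T1" targetRef="jn"/>
  <sequenceFlow id="f5" sourceRef="T2" targetRef="jn"/>
  <sequenceFlow id="f6" sourceRef="jn" targetRef="end"/>
 </process>
</definitions>
"""


class TestParseBpmn:
    def test_minimal_document(self):
        graph = parse_bpmn(linear_bpmn("T1"), {"T1": {"area": "ETR", "duration_min": 10}})
        assert len(graph.tasks) == 1
        assert graph.tasks["T1"].area_id == "ETR"
        assert graph.tasks["T1"].default_duration_min == 10.0

    def test_two_start_events_rejected(self):
        doc = linear_bpmn("T1").replace(
            '<startEvent id="start"/>',
            '<startEvent id="start"/><startEvent id="start2"/>')
        with pytest.raises(MalformedProcess):
            parse_bpmn(doc, {})

    def test_parallel_block_structure(self):
        graph = parse_bpmn(PARALLEL_DOC, {})
        assert graph.gateways["sp"].kind == "parallel_split"
        assert graph.gateways["jn"].kind == "parallel_join"
        assert {e.target for e in graph.out_edges("sp")} == {"T1", "T2"}
        assert {e.source for e in graph.in_edges("jn")} == {"T1", "T2"}

    def test_metadata_for_unknown_id_rejected(self):
        with pytest.raises(MalformedProcess):
            parse_bpmn(linear_bpmn("T1"), {"nope": {"area": "x"}})

    def test_unknown_element_strict_vs_lenient(self):
        doc = linear_bpmn("T1").replace(
            '<endEvent id="end"/>',
            '<endEvent id="end"/><subProcess id="sub"/>')
        with pytest.raises(MalformedProcess):
            parse_bpmn(doc, {}, strict=True)
        graph = parse_bpmn(doc, {}, strict=False)
        assert "sub" not in graph.node_ids()

    def test_bpmn_roundtrip(self, etr_bundle):
        graph = etr_bundle.graph
        again = parse_bpmn(
            to_bpmn(graph),
            {tid: {"area": t.area_id, "duration_min": t.default_duration_min}
             for tid, t in graph.tasks.items()},
            redundant_groups=graph.redundant_groups)
        assert set(again.tasks) == set(graph.tasks)
        assert {g: gw.kind for g, gw in again.gateways.items()} == {
            g: gw.kind for g, gw in graph.gateways.items()}
        assert sorted((e.source, e.target, e.label) for e in again.edges) == \
            sorted((e.source, e.target, e.label) for e in graph.edges)


class TestValidateProcess:
    def test_valid_fixture_graphs_are_clean(self, minimal_bundle, etr_bundle):
        assert validate_process(minimal_bundle.graph) == []
        assert validate_process(etr_bundle.graph) == []

    def test_unreachable_node_reported(self):
        graph = parse_bpmn(linear_bpmn("T1"), {})
        graph.tasks["orphan"] = graph.tasks["T1"].__class__(id="orphan")
        graph.edges.append(Edge("orphan", "end"))
        violations = validate_process(graph)
        assert any(v.startswith("unreachable: orphan") for v in violations)

    def test_unbalanced_parallel_reported(self):
        doc = PARALLEL_DOC.replace('<parallelGateway id="jn"/>',
                                   '<exclusiveGateway id="jn"/>')
        graph = parse_bpmn(doc, {})
        assert any(v.startswith("unbalanced_parallel: sp")
                   for v in validate_process(graph))

    def test_detach_without_attach_reported(self):
        graph = parse_bpmn(
            linear_bpmn("T1"),
            {"T1": {"area": "er", "duration_min": 5,
                    "demands": [{"type": "vent", "action": "detach"}]}})
        assert any("detach_without_attach" in v for v in validate_process(graph))

    def test_validation_is_idempotent(self, etr_bundle):
        assert validate_process(etr_bundle.graph) == validate_process(etr_bundle.graph)

    def test_demand_invariants(self):
        with pytest.raises(ValueError):
            ResourceDemand(resource_type_id="x", count=0)
        with pytest.raises(ValueError):
            ResourceDemand(resource_type_id="x", sub_interval=(0, 5))  # wrong mode


class TestNominalPathDuration:
    def test_single_task(self):
        graph = parse_bpmn(linear_bpmn("T1"), {"T1": {"area": "er", "duration_min": 10}})
        assert nominal_path_duration(graph, "g", one_area_hospital()) == 10.0

    def test_transit_additivity(self):
        graph = parse_bpmn(
            linear_bpmn("T1", "T2"),
            {"T1": {"area": "a", "duration_min": 10},
             "T2": {"area": "b", "duration_min": 20}})
        hospital = HospitalState(
            areas={"a": Area(id="a"), "b": Area(id="b")},
            transit=TransitMatrix.from_symmetric({("a", "b"): 5.0}),
            types={}, instances={})
        assert nominal_path_duration(graph, "g", hospital) == 35.0

    def test_parallel_max_rule(self):
        graph = parse_bpmn(PARALLEL_DOC, {
            "T1": {"area": "er", "duration_min": 10},
            "T2": {"area": "er", "duration_min": 20}})
        assert nominal_path_duration(graph, "g", one_area_hospital()) == 20.0

    def test_group_override_substitution(self):
        graph = parse_bpmn(
            linear_bpmn("T1"),
            {"T1": {"area": "er", "duration_min": 10, "overrides": {"g": 12}}})
        hosp = one_area_hospital()
        assert nominal_path_duration(graph, "g", hosp) == 12.0
        assert nominal_path_duration(graph, "other", hosp) == 10.0

    def test_unresolved_branch_raises(self):
        doc = PARALLEL_DOC.replace("parallelGateway", "exclusiveGateway")
        graph = parse_bpmn(doc, {"T1": {"area": "er", "duration_min": 1},
                                 "T2": {"area": "er", "duration_min": 2}})
        with pytest.raises(UnresolvedBranch):
            nominal_path_duration(graph, "g", one_area_hospital())

    def test_relabeling_invariance(self):
        meta = {"T1": {"area": "er", "duration_min": 7},
                "T2": {"area": "er", "duration_min": 9}}
        base = nominal_path_duration(
            parse_bpmn(linear_bpmn("T1", "T2"), meta), "g", one_area_hospital())
        renamed_meta = {"X1": meta["T1"], "X2": meta["T2"]}
        renamed = nominal_path_duration(
            parse_bpmn(linear_bpmn("X1", "X2"), renamed_meta), "g",
            one_area_hospital())
        assert base == renamed == 16.0

    def test_redundant_choice_is_globally_minimal_by_brute_force(self):
        """The per-split min-branch-sum choice equals the minimum over every
        explicit branch-choice vector (single-area graphs, where exit-transit
        asymmetry cannot decouple branch-wise and global optima)."""
        checked = 0
        for seed in range(40):
            spec = build_random_process(seed, n_areas=1)
            splits = {s: labels for s, labels in spec.graph.redundant_groups.items()}
            if not splits or len(splits) > 3:
                continue
            inline = nominal_path_duration(spec.graph, "g_rand", spec.hospital)
            brute = min(
                nominal_path_duration(
                    spec.graph, "g_rand", spec.hospital,
                    branch_choices=dict(zip(splits, combo)))
                for combo in itertools.product(*splits.values()))
            assert inline == pytest.approx(brute, abs=1e-9)
            checked += 1
        assert checked >= 10
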