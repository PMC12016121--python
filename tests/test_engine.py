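"""Engine semantics: allocation, lending, deadlines, branching, determinism."""

import pytest

from wardflow.audit import audit_log
from wardflow.engine import ScenarioSpec, simulate
from wardflow.errors import InvalidScenario
from wardflow.fixtures import build_random_process
from wardflow.hospital import (
    Area,
    HospitalState,
    Modifier,
    ResourceInstance,
    ResourceType,
    TransitMatrix,
)
from wardflow.patients import Patient
from wardflow.process import nominal_path_duration, parse_bpmn

from conftest import linear_bpmn, one_area_hospital, one_task_spec, plain_group


def events_of(result, *kinds):
    return [e for e in result.events if e.kind in kinds]


def two_area_hospital(transit=5.0, **stock):
    """Areas 'er' and 'store'; ``stock`` maps type -> (area, count)."""
    types, instances = {}, {}
    for t, (area, n) in stock.items():
        types[t] = ResourceType(id=t, category="device")
        for i in range(n):
            iid = f"{t}_{area}_{i + 1}"
            instances[iid] = ResourceInstance(id=iid, type_id=t, home_area=area)
    return HospitalState(
        areas={"er": Area(id="er"), "store": Area(id="store")},
        transit=TransitMatrix.from_symmetric({("er", "store"): transit}),
        types=types, instances=instances)


class TestSinglePatientOracle:
    def test_completion_equals_nominal_on_random_graphs(self):
        """Event-driven walk vs closed-form sum over 30 random processes."""
        for seed in range(30):
            spec = build_random_process(seed)
            out = list(simulate(spec).outcomes.values())[0]
            nominal = nominal_path_duration(spec.graph, "g_rand", spec.hospital)
            assert out["duration_min"] == pytest.approx(nominal, abs=1e-9)

    def test_minimal_fixture_runs_to_completion(self, minimal_bundle):
        res = simulate(minimal_bundle.scenarios["baseline"])
        out = list(res.outcomes.values())[0]
        assert out["completion_min"] == 12.0
        assert out["path"] == ["T1", "T2"]


class TestContentionAndQueueing:
    def test_two_patients_one_instance_complete_at_10_and_20(self):
        res = simulate(one_task_spec(duration=10.0, n_instances=1, n_patients=2))
        assert res.outcomes["P1"]["completion_min"] == 10.0
        assert res.outcomes["P2"]["completion_min"] == 20.0

    def test_priority_jumps_queue(self):
        spec = one_task_spec(duration=10.0, n_instances=1, n_patients=0)
        high = plain_group("vip", priority=9)
        spec.groups.append(high)
        spec.cohort = [
            Patient(id="P1", group_id="g", t_start_min=0.0),
            Patient(id="P2", group_id="g", t_start_min=1.0),
            Patient(id="P3", group_id="vip", t_start_min=2.0),
        ]
        res = simulate(spec)
        # P1 holds the nurse (non-preemptive); the VIP overtakes P2
        assert res.outcomes["P1"]["completion_min"] == 10.0
        assert res.outcomes["P3"]["completion_min"] == 20.0
        assert res.outcomes["P2"]["completion_min"] == 30.0

    def test_fifo_work_conservation_at_equal_priority(self):
        spec = one_task_spec(duration=7.0, n_instances=1, n_patients=0)
        spec.cohort = [Patient(id=f"P{i}", group_id="g", t_start_min=float(i))
                       for i in range(1, 7)]
        res = simulate(spec)
        completions = [res.outcomes[f"P{i}"]["completion_min"] for i in range(1, 7)]
        assert completions == sorted(completions)
        # P1 arrives at 1 and serves immediately; everyone else queues FIFO
        assert completions == [1.0 + 7.0 * i for i in range(1, 7)]


class TestLending:
    def test_borrow_with_transit_delays_task_start(self):
        graph = parse_bpmn(
            linear_bpmn("T"),
            {"T": {"area": "er", "duration_min": 10.0,
                   "demands": [{"type": "vent"}]}})
        hosp = two_area_hospital(transit=5.0, vent=("store", 1))
        spec = ScenarioSpec(graph=graph, hospital=hosp, groups=[plain_group()],
                            cohort=[Patient(id="P1", group_id="g", t_start_min=0.0)],
                            horizon_min=100)
        res = simulate(spec)
        (start,) = events_of(res, "task_start")
        assert start.time_min == 5.0
        assert res.outcomes["P1"]["completion_min"] == 15.0
        # instance returns home afterwards
        ret = events_of(res, "resource_return")[-1]
        assert ret.time_min == 20.0 and ret.payload["area"] == "store"

    def test_nearest_lender_wins(self):
        graph = parse_bpmn(
            linear_bpmn("T"),
            {"T": {"area": "er", "duration_min": 10.0,
                   "demands": [{"type": "vent"}]}})
        types = {"vent": ResourceType(id="vent")}
        instances = {
            "v_far": ResourceInstance(id="v_far", type_id="vent", home_area="far"),
            "v_near": ResourceInstance(id="v_near", type_id="vent", home_area="near"),
        }
        hosp = HospitalState(
            areas={a: Area(id=a) for a in ("er", "near", "far")},
            transit=TransitMatrix.from_symmetric(
                {("er", "near"): 5.0, ("er", "far"): 8.0, ("near", "far"): 4.0}),
            types=types, instances=instances)
        spec = ScenarioSpec(graph=graph, hospital=hosp, groups=[plain_group()],
                            cohort=[Patient(id="P1", group_id="g", t_start_min=0.0)],
                            horizon_min=100)
        res = simulate(spec)
        (dispatch,) = [e for e in events_of(res, "resource_dispatch")
                       if e.payload["purpose"] == "lend"]
        assert dispatch.payload["instance"] == "v_near"

    def test_min_stock_never_violated_by_lending(self):
        graph = parse_bpmn(
            linear_bpmn("T"),
            {"T": {"area": "er", "duration_min": 5.0,
                   "demands": [{"type": "vent"}]}})
        hosp = two_area_hospital(transit=3.0, vent=("store", 2))
        hosp.areas["store"].min_stock = {"vent": 2}
        spec = ScenarioSpec(graph=graph, hospital=hosp, groups=[plain_group()],
                            cohort=[Patient(id="P1", group_id="g", t_start_min=0.0)],
                            horizon_min=50)
        res = simulate(spec)
        # both instances protected by min stock: the request starves
        assert res.outcomes["P1"]["completion_min"] is None
        assert res.outcomes["P1"]["in_flight"]


class TestDeadlines:
    def test_ttd_flags_damage_but_patient_continues(self):
        spec = one_task_spec(duration=10.0, ttd_initial_min=4.0)
        res = simulate(spec)
        out = res.outcomes["P1"]
        assert out["damaged"] and not out["removed_reanimation"]
        assert out["completion_min"] == 10.0

    def test_completion_before_deadline_discards_event(self):
        spec = one_task_spec(duration=10.0, ttd_initial_min=60.0)
        res = simulate(spec)
        assert not res.outcomes["P1"]["damaged"]
        assert not events_of(res, "ttd_hit")

    def test_ttr_under_outage_removes_at_exact_deadline(self):
        spec = one_task_spec(duration=10.0, ttr_initial_min=5.0)
        spec.modifiers = [Modifier(0.0, "resource_outage_start", "nurse"),
                          Modifier(60.0, "resource_outage_end", "nurse")]
        res = simulate(spec)
        out = res.outcomes["P1"]
        assert out["removed_reanimation"] and out["completion_min"] is None
        (hit,) = events_of(res, "ttr_hit")
        assert hit.time_min == 5.0
        assert not events_of(res, "ttd_hit")

    def test_therapy_delta_moves_pending_deadline(self):
        graph = parse_bpmn(
            linear_bpmn("T1", "T2"),
            {"T1": {"area": "er", "duration_min": 40.0,
                    "demands": [{"type": "nurse"}], "ttd_delta_min": 30.0},
             "T2": {"area": "er", "duration_min": 30.0,
                    "demands": [{"type": "nurse"}]}})
        spec = ScenarioSpec(
            graph=graph, hospital=one_area_hospital(nurse=1),
            groups=[plain_group()],
            cohort=[Patient(id="P1", group_id="g", t_start_min=0.0,
                            ttd_initial_min=65.0)],
            horizon_min=500)
        res = simulate(spec)
        # deadline moved from 65 to 95 at T1's end (t=40); T2 ends at 70 < 95
        assert not res.outcomes["P1"]["damaged"]
        # same but without the delta: damage at 65, still completes
        graph.tasks["T1"].ttd_delta_min = 0.0
        res2 = simulate(spec)
        assert res2.outcomes["P1"]["damaged"]
        (hit,) = events_of(res2, "ttd_hit")
        assert hit.time_min == 65.0

    def test_ttr_removal_releases_held_resources(self):
        spec = one_task_spec(duration=10.0, n_patients=2, ttr_initial_min=5.0)
        # P1 grabs the nurse and is removed mid-task at t=5; P2's TTR also
        # fires at 5 before it ever got the nurse
        res = simulate(spec)
        assert all(res.outcomes[p]["removed_reanimation"] for p in ("P1", "P2"))
        nurse_states = [i.state for i in res.hospital.instances.values()]
        assert nurse_states == ["idle"]


class TestAttachDetach:
    @pytest.fixture
    def attach_spec(self):
        doc = linear_bpmn("T1", "T2", "T3")
        meta = {
            "T1": {"area": "er", "duration_min": 5.0,
                   "demands": [{"type": "vent", "action": "attach"}]},
            "T2": {"area": "er", "duration_min": 10.0,
                   "demands": [{"type": "nurse"}]},
            "T3": {"area": "er", "duration_min": 4.0,
                   "demands": [{"type": "vent", "action": "detach"}]},
        }
        graph = parse_bpmn(doc, meta)
        types = {"vent": ResourceType(id="vent", attachable=True),
                 "nurse": ResourceType(id="nurse", category="staff")}
        instances = {
            "v1": ResourceInstance(id="v1", type_id="vent", home_area="er"),
            "n1": ResourceInstance(id="n1", type_id="nurse", home_area="er")}
        hosp = HospitalState(areas={"er": Area(id="er")}, transit=TransitMatrix(),
                             types=types, instances=instances)
        return ScenarioSpec(
            graph=graph, hospital=hosp, groups=[plain_group()],
            cohort=[Patient(id="P1", group_id="g", t_start_min=0.0)],
            horizon_min=200)

    def test_attached_instance_excluded_until_detach(self, attach_spec):
        res = simulate(attach_spec)
        (end,) = [e for e in events_of(res, "task_end") if e.payload["task"] == "T3"]
        assert end.payload["detached"] == ["v1"]
        # detach in home area: idle immediately, no return transit
        ret = [e for e in events_of(res, "resource_return")
               if e.payload["instance"] == "v1"]
        assert ret[-1].time_min == end.time_min
        assert res.hospital.instances["v1"].state == "idle"

    def test_removal_while_attached_starts_return_transit(self, attach_spec):
        attach_spec.cohort[0].ttr_initial_min = 7.0  # mid-T2
        res = simulate(attach_spec)
        (hit,) = events_of(res, "ttr_hit")
        assert "v1" in hit.payload["released"]
        assert res.hospital.instances["v1"].state == "idle"

    def test_attach_not_attachable_is_invalid_scenario(self, attach_spec):
        attach_spec.hospital.types["vent"].attachable = False
        with pytest.raises(InvalidScenario):
            simulate(attach_spec)


class TestSubIntervalHold:
    def test_early_release_frees_instance_before_task_end(self):
        graph = parse_bpmn(
            linear_bpmn("T"),
            {"T": {"area": "er", "duration_min": 10.0,
                   "demands": [{"type": "nurse"},
                               {"type": "tech", "hold": "sub_interval",
                                "sub_interval": [0.0, 4.0]}]}})
        hosp = one_area_hospital(nurse=1, tech=1)
        spec = ScenarioSpec(
            graph=graph, hospital=hosp, groups=[plain_group()],
            cohort=[Patient(id="P1", group_id="g", t_start_min=0.0),
                    Patient(id="P2", group_id="g", t_start_min=0.0)],
            horizon_min=100)
        res = simulate(spec)
        rets = [e for e in events_of(res, "resource_return")
                if e.payload["instance"] == "tech_1"]
        assert rets[0].time_min == 4.0  # released mid-task
        assert res.outcomes["P1"]["completion_min"] == 10.0


class TestRedundantBranchChoice:
    def _spec(self, short=15.0, long=20.0, backlog=None):
        doc = """
        <definitions xmlns="http://www.omg.org/spec/BPMN/20100524/MODEL">
         <process id="p">
          <startEvent id="start"/>
          <exclusiveGateway id="sp"/><exclusiveGateway id="jn"/>
          <task id="A"/><task id="B"/><endEvent id="end"/>
          <sequenceFlow id="f1" sourceRef="start" targetRef="sp"/>
          <sequenceFlow id="f2" sourceRef="sp" targetRef="A" name="short"/>
          <sequenceFlow id="f3" sourceRef="sp" targetRef="B" name="long"/>
          <sequenceFlow id="f4" sourceRef="A" targetRef="jn"/>
          <sequenceFlow id="f5" sourceRef="B" targetRef="jn"/>
          <sequenceFlow id="f6" sourceRef="jn" targetRef="end"/>
         </process>
        </definitions>"""
        meta = {"A": {"area": "er", "duration_min": short,
                      "demands": [{"type": "ct"}]},
                "B": {"area": "er", "duration_min": long,
                      "demands": [{"type": "mri"}]}}
        graph = parse_bpmn(doc, meta,
                           redundant_groups={"sp": ["short", "long"]})
        hosp = one_area_hospital(ct=1, mri=1)
        cohort = [Patient(id="P1", group_id="g", t_start_min=0.0)]
        if backlog:
            cohort.insert(0, Patient(id="P0", group_id="g", t_start_min=-0.0))
        return ScenarioSpec(graph=graph, hospital=hosp, groups=[plain_group()],
                            cohort=cohort, horizon_min=500)

    def test_idle_hospital_takes_smaller_nominal_sum(self):
        res = simulate(self._spec())
        assert res.outcomes["P1"]["path"] == ["A"]
        assert res.outcomes["P1"]["completion_min"] == 15.0

    def test_equal_estimates_take_first_declared(self):
        res = simulate(self._spec(short=20.0, long=20.0))
        assert res.outcomes["P1"]["path"] == ["A"]

    def test_backlog_flips_choice_to_long_branch(self):
        """With 40 min queued on the short branch's only instance,
        15 + 40 > 20: the second patient takes the long branch."""
        spec = self._spec(short=15.0, long=20.0)
        # park a competing patient on the short branch first: both arrive at
        # 0 but P0 sorts first and occupies the ct for 15 min; P1's estimate
        # for "short" = 15 (duration) + 15 (backlog/1) = 30 > 20
        spec.cohort.insert(0, Patient(id="P0", group_id="g", t_start_min=0.0))
        spec.graph.tasks["A"].default_duration_min = 15.0
        res = simulate(spec)
        assert res.outcomes["P0"]["path"] == ["A"]
        assert res.outcomes["P1"]["path"] == ["B"]
        assert res.outcomes["P1"]["completion_min"] == 20.0


class TestModifiersInFlight:
    def test_outage_queues_demand_until_end(self):
        spec = one_task_spec(duration=10.0)
        spec.modifiers = [Modifier(0.0, "resource_outage_start", "nurse"),
                          Modifier(30.0, "resource_outage_end", "nurse")]
        res = simulate(spec)
        (start,) = events_of(res, "task_start")
        assert start.time_min == 30.0
        assert res.outcomes["P1"]["completion_min"] == 40.0

    def test_deactivated_area_blocks_execution_until_reactivation(self):
        spec = one_task_spec(duration=10.0)
        spec.modifiers = [Modifier(0.0, "deactivate_area", "er"),
                          Modifier(20.0, "reactivate_area", "er")]
        res = simulate(spec)
        assert res.outcomes["P1"]["completion_min"] == 30.0

    def test_efficiency_change_applies_to_later_starts_only(self):
        spec = one_task_spec(duration=10.0, n_patients=2)
        spec.modifiers = [Modifier(5.0, "set_efficiency", "nurse", 50.0)]
        res = simulate(spec)
        # P1 started at 0 under 100% (10 min); P2 starts at 10 under 50%
        assert res.outcomes["P1"]["completion_min"] == 10.0
        assert res.outcomes["P2"]["completion_min"] == 30.0

    def test_quarantine_freezes_resources_until_lift(self):
        spec = one_task_spec(duration=10.0, n_patients=2)
        # quarantine begins while P1's task is in flight; the task finishes
        # under the old parameters, but the released nurse is frozen in the
        # area until the lift, so P2 waits
        spec.modifiers = [Modifier(9.5, "quarantine_area", "er"),
                          Modifier(50.0, "lift_quarantine", "er")]
        res = simulate(spec)
        assert res.outcomes["P1"]["completion_min"] == 10.0
        assert res.outcomes["P2"]["completion_min"] == 60.0
        assert audit_log(res, spec) == []


class TestDeterminismAndResult:
    def test_same_spec_byte_identical_logs(self, mci_spec):
        assert simulate(mci_spec).events_jsonl() == simulate(mci_spec).events_jsonl()

    def test_input_spec_not_mutated(self, mci_spec):
        before = [p.t_start_min for p in mci_spec.cohort]
        states = [i.state for i in mci_spec.hospital.instances.values()]
        simulate(mci_spec)
        assert [p.t_start_min for p in mci_spec.cohort] == before
        assert [i.state for i in mci_spec.hospital.instances.values()] == states

    def test_log_sorted_with_unique_seq(self, mci_spec):
        res = simulate(mci_spec)
        keys = [(e.time_min, e.seq) for e in res.events]
        assert keys == sorted(keys)
        assert len({e.seq for e in res.events}) == len(res.events)

    def test_horizon_flags_in_flight_patients(self):
        spec = one_task_spec(duration=10.0)
        spec.horizon_min = 4.0
        res = simulate(spec)
        assert res.outcomes["P1"]["in_flight"]
        assert res.outcomes["P1"]["completion_min"] is None

    def test_invalid_scenario_raises_with_all_problems(self):
        spec = one_task_spec()
        spec.cohort.append(Patient(id="PX", group_id="ghost", t_start_min=0.0))
        spec.graph.tasks["T"].area_id = "nowhere"
        with pytest.raises(InvalidScenario) as err:
            simulate(spec)
        msg = str(err.value)
        assert "cohort_unknown_group" in msg and "task_unknown_area" in msg


class TestLogAudit:
    def test_mci_log_passes_all_invariants(self, mci_spec):
        res = simulate(mci_spec)
        assert audit_log(res, mci_spec) == []

    def test_audit_catches_forged_double_grant(self, mci_spec):
        res = simulate(mci_spec)
        # duplicate an alloc event so one instance is granted while busy
        import dataclasses
        grants = [e for e in res.events if e.kind == "alloc_granted"
                  and e.payload["instances"]]
        forged = dataclasses.replace(grants[0], seq=grants[0].seq)
        res.events.insert(res.events.index(grants[0]) + 2, forged)
        assert audit_log(res, mci_spec) != []
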