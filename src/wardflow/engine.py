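"""The hybrid simulation core.

Discrete-event kernel (continuous time, heap-ordered, seq tie-broken)
driving agent-based patients through a process graph.  One run is fully
determined by its :class:`ScenarioSpec`: durations are deterministic per
group, the only randomness in the pipeline is cohort generation, which is
seed-controlled upstream.  Two identically configured runs produce
byte-identical event logs.

Semantics in brief:

* A patient token walks the graph.  Tasks require the patient to be in
  the task's area (transport first), then all resource demands to be
  grantable **atomically**: local idle instances first, shortfall
  borrowed from the area with the smallest transit time among those with
  lending capacity.  Borrowed instances travel before the task starts.
* The grant queue is ordered by (priority desc, arrival asc, patient id);
  grants are non-preemptive — a running task always finishes.
* Redundant exclusive splits route each patient down the branch with the
  smallest estimated completion time (nominal branch time plus a
  backlog/in-service wait estimate per required type).
* TTD reaching zero flags the patient *damaged* (the process failed for
  them) but they continue; TTR reaching zero removes the patient and
  releases everything they hold.  Therapy tasks push both deadlines out
  at task completion.
"""

from __future__ import annotations

import heapq
import itertools
import json
import math
from dataclasses import dataclass, field
from typing import Any, Optional

from .errors import (
    AttachNotAttachable,
    DetachNotAttached,
    InvalidScenario,
)
from .hospital import (
    HospitalState,
    Modifier,
    apply_modifier,
    effective_duration,
    transit_time,
)
from .patients import InjuryGroup, Patient, effective_deadlines
from .process import (
    EXCLUSIVE_JOIN,
    EXCLUSIVE_SPLIT,
    PARALLEL_JOIN,
    PARALLEL_SPLIT,
    ProcessGraph,
    match_exclusive_join,
    match_parallel_join,
    resolve_branch,
    validate_process,
)

EVENT_KINDS = (
    "arrival", "alloc_granted", "task_start", "task_end",
    "transport_start", "transport_end", "resource_dispatch",
    "resource_return", "modifier_applied", "ttd_hit", "ttr_hit",
    "patient_completed",
)


@dataclass(frozen=True)
class Event:
    """One log record; the log is sorted by ``(time_min, seq)``."""

    time_min: float
    seq: int
    kind: str
    payload: dict[str, Any]

    def to_json(self) -> str:
        rec = {"t": self.time_min, "seq": self.seq, "kind": self.kind}
        rec.update(self.payload)
        return json.dumps(rec)


@dataclass
class ScenarioSpec:
    """Everything one reproducible run needs."""

    graph: ProcessGraph
    hospital: HospitalState
    groups: list[InjuryGroup]
    cohort: list[Patient]
    modifiers: list[Modifier] = field(default_factory=list)
    seed: int = 0
    horizon_min: float = 1e6

    def group_by_id(self, gid: str) -> InjuryGroup:
        for g in self.groups:
            if g.id == gid:
                return g
        raise KeyError(gid)

    def validate(self) -> list[str]:
        """Cross-reference checks; returns all problems, empty list if fine."""
        v = list(validate_process(self.graph))
        v += self.hospital.validate()
        gids = {g.id for g in self.groups}
        for p in self.cohort:
            if p.group_id not in gids:
                v.append(f"cohort_unknown_group: {p.id}/{p.group_id}")
        for tid in sorted(self.graph.tasks):
            t = self.graph.tasks[tid]
            if t.area_id and t.area_id not in self.hospital.areas:
                v.append(f"task_unknown_area: {tid}/{t.area_id}")
            for d in t.demands:
                if d.resource_type_id not in self.hospital.types:
                    v.append(f"demand_unknown_type: {tid}/{d.resource_type_id}")
                elif d.action == "attach" and not self.hospital.types[d.resource_type_id].attachable:
                    v.append(f"attach_not_attachable: {tid}/{d.resource_type_id}")
        for m in self.modifiers:
            if m.kind in ("set_transit",):
                a, b = tuple(m.target)
                if a not in self.hospital.areas or b not in self.hospital.areas:
                    v.append(f"modifier_unknown_area_pair: {m.target}")
            elif m.kind.endswith("_area") or m.kind in ("quarantine_area", "lift_quarantine"):
                if m.target not in self.hospital.areas:
                    v.append(f"modifier_unknown_area: {m.target}")
            else:
                if m.target not in self.hospital.types:
                    v.append(f"modifier_unknown_type: {m.target}")
        if self.cohort:
            max_arrival = max(p.t_start_min for p in self.cohort)
            if self.horizon_min <= max_arrival:
                v.append("horizon_before_last_arrival")
        return v


@dataclass
class SimulationResult:
    """Ordered event log, per-patient outcomes, final resource state."""

    events: list[Event]
    outcomes: dict[str, dict[str, Any]]
    hospital: HospitalState

    def events_jsonl(self) -> str:
        return "\n".join(e.to_json() for e in self.events) + "\n"

    def completed(self) -> list[dict[str, Any]]:
        return [o for o in self.outcomes.values() if o["completion_min"] is not None]


# ---------------------------------------------------------------------------
# Branch choice strategy
# ---------------------------------------------------------------------------

class NominalBacklogEstimator:
    """Default branch-time estimator for redundant splits.

    Estimate per branch = sum over branch tasks of (effective duration for
    the group + inbound transit) + per required resource type a wait
    estimate: minutes of work currently queued or running on that type in
    the task's area, divided by the number of in-service instances there
    (infinite when none are in service).
    """

    def estimate(self, sim: "_Simulator", token: "_Token", group: InjuryGroup,
                 split_id: str, label: str) -> float:
        graph = sim.spec.graph
        join = match_exclusive_join(graph, split_id)
        target = None
        for e in graph.out_edges(split_id):
            if e.label == label:
                target = e.target
        if target is None:
            return math.inf
        stop = join if join is not None else graph.end_id
        total = 0.0
        loc = token.loc
        cur = target
        guard = 0
        while cur != stop and cur != graph.end_id:
            guard += 1
            if guard > len(graph.edges) + 2:
                break
            kind = graph.kind_of(cur)
            if kind == "task":
                t = graph.tasks[cur]
                if loc is not None and t.area_id and t.area_id != loc:
                    total += transit_time(sim.state, loc, t.area_id)
                if t.area_id:
                    loc = t.area_id
                total += sim._estimated_task_minutes(t, group.id)
                for type_id in sorted({d.resource_type_id for d in t.demands
                                       if d.action in ("use", "attach")}):
                    total += self._wait_estimate(sim, type_id, t.area_id)
            outs = graph.out_edges(cur)
            if not outs:
                break
            cur = outs[0].target
        return total

    def _wait_estimate(self, sim: "_Simulator", type_id: str, area_id: str) -> float:
        in_service = sum(
            1 for iid in sorted(sim.state.instances)
            if sim.state.instances[iid].type_id == type_id
            and sim.state.instances[iid].location == area_id
            and sim.state.instances[iid].state in ("idle", "busy")
        )
        if in_service == 0:
            return math.inf
        backlog = 0.0
        for rt in sim.running.values():
            if rt["area"] == area_id and type_id in rt["type_ids"]:
                backlog += max(0.0, rt["end_min"] - sim.clock)
        for req in sim.queue:
            task = sim.spec.graph.tasks[req["task_id"]]
            if task.area_id == area_id and any(
                    d.resource_type_id == type_id for d in task.demands
                    if d.action in ("use", "attach")):
                backlog += sim._estimated_task_minutes(task, req["group_id"])
        return backlog / in_service


# ---------------------------------------------------------------------------
# Internal plumbing
# ---------------------------------------------------------------------------

class _Action:
    __slots__ = ("fn", "args", "cancelled")

    def __init__(self, fn, args):
        self.fn = fn
        self.args = args
        self.cancelled = False

    def cancel(self):
        self.cancelled = True


class _Token:
    __slots__ = ("pid", "node", "loc", "tid", "branch_idx")

    def __init__(self, pid, node, loc, tid):
        self.pid = pid
        self.node = node
        self.loc = loc
        self.tid = tid  # deterministic token id
        self.branch_idx = 0


class _Simulator:
    def __init__(self, spec: ScenarioSpec, estimator=None):
        self.spec = spec
        self.state: HospitalState = spec.hospital.clone()
        self.estimator = estimator or NominalBacklogEstimator()
        self.clock = 0.0
        self._heap: list = []
        self._sched_seq = itertools.count()
        self._log_seq = itertools.count()
        self.events: list[Event] = []
        self.patients: dict[str, Patient] = {}
        self._prt: dict[str, dict] = {}  # per-patient runtime bookkeeping
        self.queue: list[dict] = []  # pending allocation requests
        self.running: dict[str, dict] = {}  # token id -> running task info
        self._token_counter = itertools.count()
        self._barriers: dict[tuple[str, str], dict] = {}

    # -- kernel ------------------------------------------------------------
    def _schedule(self, time: float, fn, *args) -> _Action:
        act = _Action(fn, args)
        heapq.heappush(self._heap, (time, next(self._sched_seq), act))
        return act

    def _log(self, kind: str, payload: dict) -> None:
        self.events.append(Event(self.clock, next(self._log_seq), kind, payload))

    def run(self) -> SimulationResult:
        problems = self.spec.validate()
        if problems:
            raise InvalidScenario("; ".join(problems))

        import copy as _copy

        for m in sorted(self.spec.modifiers, key=lambda m: (m.at_min, MODIFIER_ORDER.get(m.kind, 9))):
            self._schedule(m.at_min, self._on_modifier, m)
        for p in self.spec.cohort:
            pc = _copy.deepcopy(p)
            self.patients[pc.id] = pc
            self._prt[pc.id] = {
                "tokens": 0, "ttd_handle": None, "ttr_handle": None,
                "path": [], "grants": {}, "transports": {},
            }
            self._schedule(pc.t_start_min, self._on_arrival, pc.id)

        horizon = self.spec.horizon_min
        while self._heap:
            time, _, act = self._heap[0]
            if time > horizon:
                break
            heapq.heappop(self._heap)
            if act.cancelled:
                continue
            self.clock = time
            act.fn(*act.args)

        outcomes = {}
        for pid in sorted(self.patients):
            p = self.patients[pid]
            outcomes[pid] = {
                "id": pid,
                "group_id": p.group_id,
                "t_start_min": p.t_start_min,
                "completion_min": p.completion_min,
                "duration_min": (p.completion_min - p.t_start_min
                                 if p.completion_min is not None else None),
                "damaged": p.damaged,
                "removed_reanimation": p.status == "removed_reanimation",
                "in_flight": p.status not in ("completed", "removed_reanimation"),
                "path": list(self._prt[pid]["path"]),
            }
        return SimulationResult(events=self.events, outcomes=outcomes, hospital=self.state)

    # -- arrival & graph walking -------------------------------------------
    def _on_arrival(self, pid: str) -> None:
        p = self.patients[pid]
        self._log("arrival", {"patient": pid, "group": p.group_id})
        prt = self._prt[pid]
        ttd, ttr = effective_deadlines(p)
        if ttd is not None:
            prt["ttd_handle"] = self._schedule(ttd, self._on_ttd_hit, pid)
        if ttr is not None:
            prt["ttr_handle"] = self._schedule(ttr, self._on_ttr_hit, pid)
        start_edge = self.spec.graph.out_edges(self.spec.graph.start_id)[0]
        token = _Token(pid, start_edge.target, None, next(self._token_counter))
        prt["tokens"] = 1
        self._advance(token)

    def _advance(self, token: _Token) -> None:
        p = self.patients[token.pid]
        if p.status == "removed_reanimation":
            return
        graph = self.spec.graph
        while True:
            node = token.node
            kind = graph.kind_of(node)
            if kind == "end":
                self._complete_patient(token)
                return
            if kind == "task":
                self._enter_task(token)
                return
            if kind == EXCLUSIVE_JOIN or kind == "start":
                token.node = graph.out_edges(node)[0].target
                continue
            if kind == EXCLUSIVE_SPLIT:
                group = self.spec.group_by_id(p.group_id)
                if node in graph.redundant_groups:
                    label = self._choose_redundant_branch(token, group, node)
                    edge = resolve_branch(graph, node, p.group_id, {node: label})
                else:
                    edge = resolve_branch(graph, node, p.group_id, None, group.branch_labels)
                token.node = edge.target
                continue
            if kind == PARALLEL_SPLIT:
                join = match_parallel_join(graph, node)
                outs = graph.out_edges(node)
                self._barriers[(token.pid, join)] = {
                    "expected": len(outs), "arrivals": []}
                self._prt[token.pid]["tokens"] += len(outs) - 1
                children = []
                for idx, e in enumerate(outs):
                    child = _Token(token.pid, e.target, token.loc, next(self._token_counter))
                    children.append((idx, child))
                for idx, child in children:
                    child.branch_idx = idx  # type: ignore[attr-defined]
                    self._advance_branch(child, idx, join)
                return
            if kind == PARALLEL_JOIN:
                self._arrive_at_join(token, node, getattr(token, "branch_idx", 0))
                return
            raise InvalidScenario(f"unexpected node kind {kind} at {node}")

    def _advance_branch(self, token: _Token, branch_idx: int, join: str) -> None:
        token.branch_idx = branch_idx  # type: ignore[attr-defined]
        self._advance(token)

    def _arrive_at_join(self, token: _Token, join: str, branch_idx: int) -> None:
        barrier = self._barriers[(token.pid, join)]
        barrier["arrivals"].append((self.clock, branch_idx, token.loc))
        self._prt[token.pid]["tokens"] -= 1
        if len(barrier["arrivals"]) == barrier["expected"]:
            del self._barriers[(token.pid, join)]
            # exit location: the branch that finished last; ties go to the
            # lowest branch index, matching the nominal max rule
            best = max(barrier["arrivals"], key=lambda a: (a[0], -a[1]))
            merged = _Token(token.pid, self.spec.graph.out_edges(join)[0].target,
                            best[2], next(self._token_counter))
            self._prt[token.pid]["tokens"] += 1
            self._advance(merged)

    def _complete_patient(self, token: _Token) -> None:
        p = self.patients[token.pid]
        prt = self._prt[token.pid]
        prt["tokens"] -= 1
        p.status = "completed"
        p.completion_min = self.clock
        for key in ("ttd_handle", "ttr_handle"):
            if prt[key] is not None:
                prt[key].cancel()
                prt[key] = None
        # anything still attached goes home when treatment ends
        self._release_attached(p, token.loc)
        self._log("patient_completed", {"patient": token.pid,
                                        "path": list(prt["path"])})
        self._try_grant_all()

    # -- transport ---------------------------------------------------------
    def _enter_task(self, token: _Token) -> None:
        task = self.spec.graph.tasks[token.node]
        p = self.patients[token.pid]
        if token.loc is None:
            token.loc = task.area_id
        if task.area_id and token.loc != task.area_id:
            dur = transit_time(self.state, token.loc, task.area_id)
            self._log("transport_start", {"patient": token.pid, "from": token.loc,
                                          "to": task.area_id})
            p.status = "in_transit"
            h = self._schedule(self.clock + dur, self._on_transport_end,
                               token, token.loc, task.area_id)
            self._prt[token.pid]["transports"][token.tid] = h
            return
        self._request_allocation(token, task)

    def _on_transport_end(self, token: _Token, src: str, dst: str) -> None:
        p = self.patients[token.pid]
        self._prt[token.pid]["transports"].pop(token.tid, None)
        token.loc = dst
        for iid in sorted(p.attached_resources):
            self.state.instances[iid].location = dst
        self._log("transport_end", {"patient": token.pid, "from": src, "to": dst})
        p.status = "waiting"
        self._request_allocation(token, self.spec.graph.tasks[token.node])

    # -- allocation --------------------------------------------------------
    def _request_allocation(self, token: _Token, task) -> None:
        p = self.patients[token.pid]
        group = self.spec.group_by_id(p.group_id)
        self.queue.append({
            "patient": token.pid,
            "token": token,
            "task_id": task.id,
            "group_id": p.group_id,
            "priority": group.priority,
            "arrival_min": p.t_start_min,
            "enqueued_at": self.clock,
        })
        self._try_grant_all()

    def _queue_key(self, req: dict):
        return (-req["priority"], req["arrival_min"], req["patient"], req["task_id"])

    def _try_grant_all(self) -> None:
        progressed = True
        while progressed:
            progressed = False
            for req in sorted(self.queue, key=self._queue_key):
                plan = self._plan(req)
                if plan is not None:
                    self.queue.remove(req)
                    self._commit(req, plan)
                    progressed = True
                    break  # re-sort: state changed

    def _plan(self, req: dict) -> Optional[list]:
        """All-or-nothing feasibility check; returns the instance plan."""
        task = self.spec.graph.tasks[req["task_id"]]
        area_id = task.area_id
        area = self.state.areas[area_id]
        if not area.active or area.quarantined:
            return None
        reserved: set[str] = set()
        plan = []
        for d in task.demands:
            if d.action == "detach":
                continue
            type_id = d.resource_type_id
            rtype = self.state.types[type_id]
            if d.action == "attach" and not rtype.attachable:
                raise AttachNotAttachable(f"{task.id}: type {type_id} is not attachable")
            if type_id in self.state.outages:
                return None
            picks: list[tuple[str, str, float]] = []  # (iid, from_area, transit)
            local = [iid for iid in sorted(self.state.instances)
                     if self.state.instances[iid].type_id == type_id
                     and self.state.instances[iid].location == area_id
                     and self.state.instances[iid].state == "idle"
                     and iid not in reserved]
            for iid in local[:d.count]:
                picks.append((iid, area_id, 0.0))
            shortfall = d.count - len(picks)
            if shortfall > 0 and rtype.mobility != "stationary":
                lenders = []
                for b in sorted(self.state.areas):
                    if b == area_id:
                        continue
                    avail = self._lendable_excluding(b, type_id, reserved)
                    if avail > 0:
                        lenders.append((transit_time(self.state, b, area_id), b, avail))
                for t_b, b, avail in sorted(lenders):
                    if shortfall <= 0:
                        break
                    cands = [iid for iid in sorted(self.state.instances)
                             if self.state.instances[iid].type_id == type_id
                             and self.state.instances[iid].location == b
                             and self.state.instances[iid].state == "idle"
                             and iid not in reserved]
                    take = min(shortfall, avail, len(cands))
                    for iid in cands[:take]:
                        picks.append((iid, b, t_b))
                    shortfall -= take
            if shortfall > 0:
                return None
            reserved.update(iid for iid, _, _ in picks)
            plan.append((d, picks))
        return plan

    def _lendable_excluding(self, area_id: str, type_id: str, reserved: set[str]) -> int:
        from .hospital import lendable_count
        base = lendable_count(self.state, area_id, type_id)
        held = sum(1 for iid in reserved
                   if self.state.instances[iid].type_id == type_id
                   and self.state.instances[iid].location == area_id)
        return max(0, base - held)

    def _commit(self, req: dict, plan: list) -> None:
        task = self.spec.graph.tasks[req["task_id"]]
        token = req["token"]
        area_id = task.area_id
        borrowed = []
        all_iids = []
        max_transit = 0.0
        for d, picks in plan:
            for iid, src, t_transit in picks:
                inst = self.state.instances[iid]
                all_iids.append(iid)
                if src == area_id:
                    inst.state = "busy"
                else:
                    inst.state = "in_transit"
                    arrive = self.clock + t_transit
                    borrowed.append({"instance": iid, "from": src, "to": area_id,
                                     "arrive_min": arrive})
                    self._log("resource_dispatch", {
                        "instance": iid, "type": inst.type_id, "from": src,
                        "to": area_id, "arrive_min": arrive, "purpose": "lend"})
                    max_transit = max(max_transit, t_transit)
        start_min = self.clock + max_transit
        self._log("alloc_granted", {
            "patient": req["patient"], "task": task.id, "area": area_id,
            "instances": sorted(all_iids), "start_min": start_min})
        grant = {"req": req, "plan": plan, "borrowed": borrowed,
                 "instances": all_iids, "start_handle": None,
                 "end_handle": None, "early_handles": []}
        self._prt[req["patient"]]["grants"][token.tid] = grant
        # register the committed work immediately so the branch-wait
        # estimator sees granted-but-not-yet-started tasks as backlog
        self.running[token.tid] = {
            "task_id": task.id, "area": area_id,
            "type_ids": sorted({d.resource_type_id for d, _ in plan}),
            "end_min": start_min + self._estimated_task_minutes(task, req["group_id"]),
            "grant": grant, "patient": req["patient"],
        }
        grant["start_handle"] = self._schedule(start_min, self._on_task_start, grant)

    def _effective_factor(self, iids: list[str]) -> float:
        effs = [self.state.instances[i].efficiency_pct for i in iids]
        return min(effs) if effs else 100.0

    def _estimated_task_minutes(self, task, group_id: str) -> float:
        """Nominal duration scaled by current worst efficiency of demanded types."""
        eff = 100.0
        for d in task.demands:
            if d.action == "detach":
                continue
            insts = self.state.instances_of(d.resource_type_id)
            if insts:
                eff = min(eff, min(i.efficiency_pct for i in insts))
        return effective_duration(task.duration_for(group_id), eff)

    def _on_task_start(self, grant: dict) -> None:
        req = grant["req"]
        token = req["token"]
        task = self.spec.graph.tasks[req["task_id"]]
        p = self.patients[req["patient"]]
        area_id = task.area_id
        attach_iids = []
        for d, picks in grant["plan"]:
            for iid, src, _ in picks:
                inst = self.state.instances[iid]
                inst.location = area_id
                if d.action == "attach":
                    inst.state = "attached"
                    attach_iids.append(iid)
                    p.attached_resources.add(iid)
                else:
                    inst.state = "busy"
        eff = self._effective_factor(grant["instances"])
        duration = effective_duration(task.duration_for(p.group_id), eff)
        end_min = self.clock + duration
        p.status = "in_task"
        self._prt[p.id]["path"].append(task.id)
        self._log("task_start", {
            "patient": p.id, "task": task.id, "area": area_id,
            "instances": sorted(grant["instances"]),
            "attached": sorted(attach_iids), "duration_min": duration})
        self.running[token.tid]["end_min"] = end_min  # firm up the estimate
        for d, picks in grant["plan"]:
            if d.hold_mode == "sub_interval" and d.action == "use":
                off, length = d.sub_interval
                rel_at = self.clock + min(duration, effective_duration(off + length, eff))
                iids = [iid for iid, _, _ in picks]
                h = self._schedule(rel_at, self._on_early_release, grant, iids)
                grant["early_handles"].append((h, iids))
        grant["end_handle"] = self._schedule(end_min, self._on_task_end, grant)

    def _on_early_release(self, grant: dict, iids: list[str]) -> None:
        grant["released_early"] = grant.get("released_early", set()) | set(iids)
        for iid in iids:
            self._release_instance(iid)
        self._try_grant_all()

    def _on_task_end(self, grant: dict) -> None:
        req = grant["req"]
        token = req["token"]
        task = self.spec.graph.tasks[req["task_id"]]
        p = self.patients[req["patient"]]
        prt = self._prt[p.id]
        self.running.pop(token.tid, None)
        prt["grants"].pop(token.tid, None)

        released, detached = [], []
        early = grant.get("released_early", set())
        for d, picks in grant["plan"]:
            if d.action == "use":
                for iid, _, _ in picks:
                    if iid not in early:
                        released.append(iid)
        for d in task.demands:
            if d.action == "detach":
                for _ in range(d.count):
                    cands = sorted(
                        iid for iid in p.attached_resources
                        if self.state.instances[iid].type_id == d.resource_type_id)
                    if not cands:
                        raise DetachNotAttached(
                            f"{task.id}: patient {p.id} has no attached "
                            f"{d.resource_type_id}")
                    iid = cands[0]
                    p.attached_resources.discard(iid)
                    detached.append(iid)

        self._log("task_end", {
            "patient": p.id, "task": task.id, "area": task.area_id,
            "released": sorted(released), "detached": sorted(detached),
            "ttd_delta_min": task.ttd_delta_min, "ttr_delta_min": task.ttr_delta_min})

        if task.ttd_delta_min or task.ttr_delta_min:
            p.delta_log.append((task.id, task.ttd_delta_min, task.ttr_delta_min))
            self._reschedule_deadlines(p.id)

        for iid in released + detached:
            self._release_instance(iid)

        p.status = "waiting"
        token.node = self.spec.graph.out_edges(task.id)[0].target
        self._advance(token)
        self._try_grant_all()

    # -- releases & returns -------------------------------------------------
    def _release_instance(self, iid: str) -> None:
        """Free an instance at its current location; send it home if borrowed."""
        inst = self.state.instances[iid]
        here = inst.location
        # a quarantined area freezes everything inside it: settle (blocked)
        # in place instead of leaving; sent home after the lift
        if here == inst.home_area or self.state.areas[here].quarantined:
            self._settle_instance(iid, here)
        else:
            dur = transit_time(self.state, here, inst.home_area)
            inst.state = "in_transit"
            arrive = self.clock + dur
            self._log("resource_dispatch", {
                "instance": iid, "type": inst.type_id, "from": here,
                "to": inst.home_area, "arrive_min": arrive, "purpose": "return"})
            self._schedule(arrive, self._on_return_home, iid)

    def _settle_instance(self, iid: str, area_id: str) -> None:
        inst = self.state.instances[iid]
        inst.location = area_id
        if inst.type_id in self.state.outages or self.state.areas[area_id].quarantined:
            inst.state = "blocked"
            self._log("resource_return", {"instance": iid, "area": area_id,
                                          "state": "blocked"})
        else:
            inst.state = "idle"
            self._log("resource_return", {"instance": iid, "area": area_id,
                                          "state": "idle"})

    def _on_return_home(self, iid: str) -> None:
        self._settle_instance(iid, self.state.instances[iid].home_area)
        self._try_grant_all()

    def _release_attached(self, p: Patient, loc: Optional[str]) -> None:
        for iid in sorted(p.attached_resources):
            inst = self.state.instances[iid]
            if loc is not None:
                inst.location = loc
            self._release_instance(iid)
        p.attached_resources.clear()

    # -- deadlines ----------------------------------------------------------
    def _reschedule_deadlines(self, pid: str) -> None:
        p = self.patients[pid]
        prt = self._prt[pid]
        ttd, ttr = effective_deadlines(p, p.delta_log)
        if prt["ttd_handle"] is not None and ttd is not None:
            prt["ttd_handle"].cancel()
            prt["ttd_handle"] = self._schedule(max(self.clock, ttd), self._on_ttd_hit, pid)
        if prt["ttr_handle"] is not None and ttr is not None:
            prt["ttr_handle"].cancel()
            prt["ttr_handle"] = self._schedule(max(self.clock, ttr), self._on_ttr_hit, pid)

    def _on_ttd_hit(self, pid: str) -> None:
        p = self.patients[pid]
        if p.status in ("completed", "removed_reanimation"):
            return
        p.damaged = True
        self._prt[pid]["ttd_handle"] = None
        self._log("ttd_hit", {"patient": pid})

    def _on_ttr_hit(self, pid: str) -> None:
        p = self.patients[pid]
        if p.status in ("completed", "removed_reanimation"):
            return
        prt = self._prt[pid]
        prt["ttr_handle"] = None
        if prt["ttd_handle"] is not None:
            prt["ttd_handle"].cancel()
            prt["ttd_handle"] = None
        released: list[str] = []
        # cancel queued requests
        self.queue = [r for r in self.queue if r["patient"] != pid]
        # cancel transports
        for h in prt["transports"].values():
            h.cancel()
        prt["transports"].clear()
        # unwind grants (reserved, travelling or running)
        for tid, grant in sorted(prt["grants"].items()):
            for key in ("start_handle", "end_handle"):
                if grant[key] is not None:
                    grant[key].cancel()
            for h, _ in grant["early_handles"]:
                h.cancel()
            early = grant.get("released_early", set())
            for d, picks in grant["plan"]:
                for iid, src, _ in picks:
                    if iid in early or iid in p.attached_resources:
                        continue
                    inst = self.state.instances[iid]
                    if inst.state == "in_transit":
                        # still travelling toward the task; let it arrive,
                        # then send it home
                        for b in grant["borrowed"]:
                            if b["instance"] == iid:
                                self._schedule(b["arrive_min"],
                                               self._on_cancelled_lend_arrival,
                                               iid, b["to"])
                    else:
                        released.append(iid)
                        self._release_instance(iid)
            self.running.pop(tid, None)
        prt["grants"].clear()
        self._barriers = {k: v for k, v in self._barriers.items() if k[0] != pid}
        released += sorted(p.attached_resources)
        self._release_attached(p, None)
        p.status = "removed_reanimation"
        prt["tokens"] = 0
        self._log("ttr_hit", {"patient": pid, "released": sorted(released)})
        self._try_grant_all()

    def _on_cancelled_lend_arrival(self, iid: str, area_id: str) -> None:
        self.state.instances[iid].location = area_id
        self._release_instance(iid)
        self._try_grant_all()

    # -- modifiers ----------------------------------------------------------
    def _on_modifier(self, m: Modifier) -> None:
        apply_modifier(self.state, m)
        self._log("modifier_applied", {
            "kind": m.kind,
            "target": list(m.target) if isinstance(m.target, tuple) else m.target,
            "value": m.value})
        if m.kind == "lift_quarantine":
            # freed instances stranded away from home head back
            for iid in sorted(self.state.instances):
                inst = self.state.instances[iid]
                if (inst.location == m.target and inst.state == "idle"
                        and inst.home_area != inst.location):
                    self._release_instance(iid)
        if m.kind in ("reactivate_area", "lift_quarantine", "resource_outage_end",
                      "set_efficiency", "set_transit"):
            self._try_grant_all()

    # -- redundant branch choice --------------------------------------------
    def _choose_redundant_branch(self, token: _Token, group: InjuryGroup,
                                 split_id: str) -> str:
        labels = self.spec.graph.redundant_groups[split_id]
        best_label = labels[0]
        best_est = math.inf
        for label in labels:  # declaration order; strict < keeps first on ties
            est = self.estimator.estimate(self, token, group, split_id, label)
            if est < best_est:
                best_est = est
                best_label = label
        return best_label


MODIFIER_ORDER = {k: i for i, k in enumerate((
    "resource_outage_end", "reactivate_area", "lift_quarantine",
    "set_transit", "set_efficiency",
    "deactivate_area", "quarantine_area", "resource_outage_start",
))}


def simulate(spec: ScenarioSpec, estimator=None) -> SimulationResult:
    """Run one scenario to completion (or horizon); fully deterministic.

    The input ``spec`` is never mutated: hospital state and cohort are
    deep-copied into the simulator.
    """
    return _Simulator(spec, estimator=estimator).run()


def choose_redundant_branch(spec: ScenarioSpec, patient: Patient, group: InjuryGroup,
                            split_id: str, estimator=None) -> str:
    """Standalone branch choice against a fresh simulator state (for tooling)."""
    sim = _Simulator(spec, estimator=estimator)
    token = _Token(patient.id, split_id, None, 0)
    return sim._choose_redundant_branch(token, group, split_id)
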