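"""Event-log auditor.

Replays a simulation's event log against the scenario's static
configuration and independently re-derives resource state, checking the
structural invariants the engine is supposed to preserve:

* **Conservation** — at every event, each resource type's instances are in
  exactly one of the five states and the per-state counts sum to the
  configured inventory.
* **Min-stock safety** — no lending dispatch leaves the lender's idle
  count below its configured minimum stock at dispatch time.
* **Quarantine hermeticity** — between a quarantine and its lift, no
  allocation, dispatch or task event involves an instance inside the
  quarantined area.
* **Non-preemption** — an instance's occupation intervals
  (grant → release) never overlap across tasks.

The auditor is deliberately independent of the engine's internals: it
sees only the log and the spec, so an engine bookkeeping bug cannot hide
itself.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable

from .engine import Event, ScenarioSpec, SimulationResult

STATES = ("idle", "busy", "in_transit", "attached", "blocked")


def audit_log(result: SimulationResult, spec: ScenarioSpec) -> list[str]:
    """Return a list of invariant violations (empty when the log is clean)."""
    violations: list[str] = []
    hosp = spec.hospital

    # independent state mirror
    state = {iid: "idle" for iid in hosp.instances}
    location = {iid: hosp.instances[iid].location for iid in hosp.instances}
    quarantined: set[str] = {a for a in hosp.areas if hosp.areas[a].quarantined}
    total_by_type = defaultdict(int)
    for iid, inst in hosp.instances.items():
        total_by_type[inst.type_id] += 1
    type_of = {iid: hosp.instances[iid].type_id for iid in hosp.instances}
    home_of = {iid: hosp.instances[iid].home_area for iid in hosp.instances}
    min_stock = {a: dict(hosp.areas[a].min_stock) for a in hosp.areas}
    outages: set[str] = set()
    busy_since: dict[str, float] = {}  # instance -> grant time of current occupation

    def idle_count(area: str, type_id: str) -> int:
        return sum(1 for iid in state
                   if state[iid] == "idle" and location[iid] == area
                   and type_of[iid] == type_id)

    def check_conservation(ev: Event) -> None:
        per_type = defaultdict(int)
        for iid, st in state.items():
            if st not in STATES:
                violations.append(f"t={ev.time_min} illegal state {st} for {iid}")
            per_type[type_of[iid]] += 1
        for tid, n in total_by_type.items():
            if per_type[tid] != n:
                violations.append(
                    f"t={ev.time_min} conservation broken for {tid}: {per_type[tid]} != {n}")

    last_time = None
    for ev in result.events:
        if last_time is not None and (ev.time_min, ev.seq) < last_time:
            violations.append(f"log out of order at seq {ev.seq}")
        last_time = (ev.time_min, ev.seq)
        pl = ev.payload

        if ev.kind == "modifier_applied":
            kind, target = pl["kind"], pl["target"]
            if kind == "quarantine_area":
                quarantined.add(target)
                for iid in state:
                    if location[iid] == target and state[iid] == "idle":
                        state[iid] = "blocked"
            elif kind == "lift_quarantine":
                quarantined.discard(target)
                for iid in state:
                    if (location[iid] == target and state[iid] == "blocked"
                            and type_of[iid] not in outages):
                        state[iid] = "idle"
            elif kind == "resource_outage_start":
                outages.add(target)
                for iid in state:
                    if type_of[iid] == target and state[iid] == "idle":
                        state[iid] = "blocked"
            elif kind == "resource_outage_end":
                outages.discard(target)
                for iid in state:
                    if (type_of[iid] == target and state[iid] == "blocked"
                            and location[iid] not in quarantined):
                        state[iid] = "idle"

        elif ev.kind == "resource_dispatch":
            iid = pl["instance"]
            src = pl["from"]
            if src in quarantined:
                violations.append(
                    f"t={ev.time_min} hermeticity: dispatch of {iid} out of quarantined {src}")
            if pl["purpose"] == "lend":
                if state[iid] != "idle":
                    violations.append(
                        f"t={ev.time_min} lend of non-idle instance {iid} ({state[iid]})")
                state[iid] = "in_transit"
                remaining = idle_count(src, type_of[iid])
                floor = min_stock.get(src, {}).get(type_of[iid], 0)
                if remaining < floor:
                    violations.append(
                        f"t={ev.time_min} min-stock broken in {src} for {type_of[iid]}: "
                        f"{remaining} < {floor}")
                busy_since[iid] = ev.time_min
            else:  # return
                state[iid] = "in_transit"
                busy_since.pop(iid, None)

        elif ev.kind == "resource_return":
            iid = pl["instance"]
            state[iid] = pl["state"]
            location[iid] = pl["area"]
            busy_since.pop(iid, None)

        elif ev.kind == "alloc_granted":
            area = pl["area"]
            if area in quarantined:
                violations.append(f"t={ev.time_min} hermeticity: grant in quarantined {area}")
            for iid in pl["instances"]:
                if state[iid] == "idle":
                    if location[iid] in quarantined:
                        violations.append(
                            f"t={ev.time_min} hermeticity: grant uses {iid} "
                            f"inside quarantined {location[iid]}")
                    state[iid] = "busy"
                    busy_since[iid] = ev.time_min
                elif state[iid] == "in_transit":
                    pass  # lent instance en route, dispatch already seen
                else:
                    violations.append(
                        f"t={ev.time_min} non-preemption: grant of occupied {iid} "
                        f"({state[iid]}) since t={busy_since.get(iid)}")

        elif ev.kind == "task_start":
            area = pl["area"]
            for iid in pl["instances"]:
                location[iid] = area
                state[iid] = "attached" if iid in set(pl["attached"]) else "busy"

        elif ev.kind == "task_end":
            # released/detached instances transition via the dispatch /
            # return events that follow; nothing to mirror here
            pass

        check_conservation(ev)

    return violations
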