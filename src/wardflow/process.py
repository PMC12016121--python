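"""Process definitions: tasks, branching, redundancy, nominal durations.

A clinical process is a directed graph with exactly one start and one end
event.  Interior nodes are either *tasks* (an action ``A`` performed in an
area ``A_r`` with a duration ``D`` and resource demands ``R``) or
*gateways* that split/join the flow exclusively (conditional on the
patient's injury group) or in parallel.  Exclusive splits may be marked
*redundant*: the simulation then routes each patient down the branch with
the smallest estimated completion time instead of a fixed per-group label.

The module reads a pragmatic subset of BPMN 2.0 XML; task metadata
(area, durations, demands, deadline deltas) lives in a sidecar mapping
keyed by the BPMN task id, because BPMN itself carries no such schema.
"""

from __future__ import annotations

import io
import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .errors import MalformedProcess, UnresolvedBranch

log = logging.getLogger(__name__)

#: Gateway kinds used throughout the package.
EXCLUSIVE_SPLIT = "exclusive_split"
EXCLUSIVE_JOIN = "exclusive_join"
PARALLEL_SPLIT = "parallel_split"
PARALLEL_JOIN = "parallel_join"

_SUPPORTED_BPMN = {
    "process",
    "startEvent",
    "endEvent",
    "task",
    "exclusiveGateway",
    "parallelGateway",
    "sequenceFlow",
    # structural containers that carry no semantics for us
    "definitions",
    "incoming",
    "outgoing",
}


@dataclass(frozen=True)
class ResourceDemand:
    """One resource requirement of a task.

    ``action`` is ``use`` (held for the task), ``attach`` (instance stays
    with the patient afterwards) or ``detach`` (a previously attached
    instance of this type is released at task end).  ``hold_mode``
    ``full_task`` ties the instance up for the whole task (the simplified
    timing mode); ``sub_interval`` releases it after
    ``offset_min + length_min`` minutes into the task (fine-grained mode).
    """

    resource_type_id: str
    count: int = 1
    hold_mode: str = "full_task"
    sub_interval: Optional[tuple[float, float]] = None  # (offset_min, length_min)
    action: str = "use"

    def __post_init__(self):
        if self.count < 1:
            raise ValueError(f"demand count must be >= 1, got {self.count}")
        if self.hold_mode not in ("full_task", "sub_interval"):
            raise ValueError(f"unknown hold_mode {self.hold_mode!r}")
        if self.action not in ("use", "attach", "detach"):
            raise ValueError(f"unknown demand action {self.action!r}")
        if (self.sub_interval is not None) != (self.hold_mode == "sub_interval"):
            raise ValueError("sub_interval must be given iff hold_mode='sub_interval'")


@dataclass
class TaskNode:
    """A process action bound to an area, with duration and demands."""

    id: str
    name: str = ""
    area_id: str = ""
    default_duration_min: float = 0.0
    demands: list[ResourceDemand] = field(default_factory=list)
    group_duration_overrides: dict[str, float] = field(default_factory=dict)
    ttd_delta_min: float = 0.0
    ttr_delta_min: float = 0.0

    def duration_for(self, group_id: Optional[str]) -> float:
        """Effective nominal duration: per-group override if present, else default."""
        if group_id is not None and group_id in self.group_duration_overrides:
            return self.group_duration_overrides[group_id]
        return self.default_duration_min


@dataclass(frozen=True)
class Gateway:
    id: str
    kind: str  # one of the four gateway kinds above


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    label: Optional[str] = None  # branch label on edges out of exclusive splits


@dataclass
class ProcessGraph:
    """The process ``P_r``: tasks, gateways, flow edges and redundancy marks.

    ``redundant_groups`` maps an exclusive-split id to the ordered list of
    branch labels that are alternatives for the same clinical purpose;
    declaration order is the tie-break for the runtime branch chooser.
    """

    tasks: dict[str, TaskNode]
    gateways: dict[str, Gateway]
    edges: list[Edge]
    start_id: str
    end_id: str
    redundant_groups: dict[str, list[str]] = field(default_factory=dict)

    # -- structural helpers -------------------------------------------------
    def out_edges(self, node_id: str) -> list[Edge]:
        return [e for e in self.edges if e.source == node_id]

    def in_edges(self, node_id: str) -> list[Edge]:
        return [e for e in self.edges if e.target == node_id]

    def node_ids(self) -> set[str]:
        return set(self.tasks) | set(self.gateways) | {self.start_id, self.end_id}

    def kind_of(self, node_id: str) -> str:
        if node_id == self.start_id:
            return "start"
        if node_id == self.end_id:
            return "end"
        if node_id in self.tasks:
            return "task"
        if node_id in self.gateways:
            return self.gateways[node_id].kind
        raise KeyError(node_id)


# ---------------------------------------------------------------------------
# BPMN reading / writing
# ---------------------------------------------------------------------------

def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _demand_from_meta(d: Mapping) -> ResourceDemand:
    sub = d.get("sub_interval")
    return ResourceDemand(
        resource_type_id=d["type"],
        count=int(d.get("count", 1)),
        hold_mode=d.get("hold", "sub_interval" if sub is not None else "full_task"),
        sub_interval=tuple(sub) if sub is not None else None,
        action=d.get("action", "use"),
    )


def parse_bpmn(
    document: str,
    task_meta: Mapping[str, Mapping],
    redundant_groups: Optional[Mapping[str, Iterable[str]]] = None,
    strict: bool = True,
) -> ProcessGraph:
    """Parse a BPMN 2.0 XML document plus sidecar task metadata.

    Supported elements: ``process``, ``startEvent``, ``endEvent``,
    ``task``, ``exclusiveGateway``, ``parallelGateway``, ``sequenceFlow``.
    Anything else raises :class:`MalformedProcess` in strict mode and is
    ignored with a warning otherwise.  ``sequenceFlow/@name`` becomes the
    branch label of the edge.

    ``task_meta`` maps a BPMN task id to a mapping with keys ``area``,
    ``duration_min``, ``demands`` (list of demand mappings with keys
    ``type``/``count``/``action``/``hold``/``sub_interval``),
    ``overrides`` (group id -> minutes), ``ttd_delta_min``,
    ``ttr_delta_min`` and optionally ``name``.
    """
    try:
        root = ET.fromstring(document)
    except ET.ParseError as exc:
        raise MalformedProcess(f"not well-formed XML: {exc}") from exc

    processes = [el for el in root.iter() if _localname(el.tag) == "process"]
    if _localname(root.tag) == "process":
        processes = [root]
    if len(processes) != 1:
        raise MalformedProcess(f"expected exactly one process element, found {len(processes)}")
    proc = processes[0]

    starts: list[str] = []
    ends: list[str] = []
    tasks: dict[str, TaskNode] = {}
    gateway_elems: dict[str, str] = {}  # id -> exclusive|parallel
    flows: list[tuple[str, str, Optional[str]]] = []

    for el in proc:
        tag = _localname(el.tag)
        if tag == "startEvent":
            starts.append(el.get("id"))
        elif tag == "endEvent":
            ends.append(el.get("id"))
        elif tag == "task":
            tid = el.get("id")
            tasks[tid] = TaskNode(id=tid, name=el.get("name", "") or "")
        elif tag == "exclusiveGateway":
            gateway_elems[el.get("id")] = "exclusive"
        elif tag == "parallelGateway":
            gateway_elems[el.get("id")] = "parallel"
        elif tag == "sequenceFlow":
            flows.append((el.get("sourceRef"), el.get("targetRef"), el.get("name") or None))
        elif tag in _SUPPORTED_BPMN:
            continue
        else:
            if strict:
                raise MalformedProcess(f"unsupported BPMN element <{tag}> in strict mode")
            log.warning("ignoring unsupported BPMN element <%s>", tag)

    if len(starts) != 1:
        raise MalformedProcess(f"expected exactly one startEvent, found {len(starts)}")
    if len(ends) != 1:
        raise MalformedProcess(f"expected exactly one endEvent, found {len(ends)}")

    edges = [Edge(s, t, lbl) for s, t, lbl in flows]
    out_deg = {gid: sum(1 for e in edges if e.source == gid) for gid in gateway_elems}
    in_deg = {gid: sum(1 for e in edges if e.target == gid) for gid in gateway_elems}
    gateways: dict[str, Gateway] = {}
    for gid, flavour in gateway_elems.items():
        if out_deg[gid] > 1 and in_deg[gid] > 1:
            raise MalformedProcess(f"gateway {gid} both splits and joins; model it as two gateways")
        kind = ("%s_split" if out_deg[gid] > 1 else "%s_join") % flavour
        gateways[gid] = Gateway(id=gid, kind=kind)

    for tid, meta in task_meta.items():
        if tid not in tasks:
            raise MalformedProcess(f"task metadata for unknown id {tid!r}")
        node = tasks[tid]
        node.area_id = meta.get("area", node.area_id)
        node.default_duration_min = float(meta.get("duration_min", node.default_duration_min))
        node.ttd_delta_min = float(meta.get("ttd_delta_min", 0.0))
        node.ttr_delta_min = float(meta.get("ttr_delta_min", 0.0))
        node.group_duration_overrides = {
            str(g): float(v) for g, v in (meta.get("overrides") or {}).items()
        }
        node.demands = [_demand_from_meta(d) for d in (meta.get("demands") or [])]
        if meta.get("name"):
            node.name = meta["name"]

    return ProcessGraph(
        tasks=tasks,
        gateways=gateways,
        edges=edges,
        start_id=starts[0],
        end_id=ends[0],
        redundant_groups={k: list(v) for k, v in (redundant_groups or {}).items()},
    )


def to_bpmn(graph: ProcessGraph) -> str:
    """Serialize the graph back to a minimal BPMN 2.0 document.

    Only structure is written (events, tasks, gateways, flows with branch
    labels); task metadata stays in the sidecar config, mirroring
    :func:`parse_bpmn`.
    """
    ns = "http://www.omg.org/spec/BPMN/20100524/MODEL"
    ET.register_namespace("bpmn", ns)
    defs = ET.Element(f"{{{ns}}}definitions")
    proc = ET.SubElement(defs, f"{{{ns}}}process", {"id": "process_1"})
    ET.SubElement(proc, f"{{{ns}}}startEvent", {"id": graph.start_id})
    for tid in sorted(graph.tasks):
        attrs = {"id": tid}
        if graph.tasks[tid].name:
            attrs["name"] = graph.tasks[tid].name
        ET.SubElement(proc, f"{{{ns}}}task", attrs)
    for gid in sorted(graph.gateways):
        flavour = "exclusiveGateway" if "exclusive" in graph.gateways[gid].kind else "parallelGateway"
        ET.SubElement(proc, f"{{{ns}}}{flavour}", {"id": gid})
    ET.SubElement(proc, f"{{{ns}}}endEvent", {"id": graph.end_id})
    for i, e in enumerate(graph.edges):
        attrs = {"id": f"flow_{i}", "sourceRef": e.source, "targetRef": e.target}
        if e.label:
            attrs["name"] = e.label
        ET.SubElement(proc, f"{{{ns}}}sequenceFlow", attrs)
    buf = io.BytesIO()
    ET.ElementTree(defs).write(buf, xml_declaration=True, encoding="utf-8")
    return buf.getvalue().decode("utf-8")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _reachable(graph: ProcessGraph, src: str, forward: bool = True) -> set[str]:
    seen = {src}
    stack = [src]
    while stack:
        cur = stack.pop()
        nxt = (e.target for e in graph.out_edges(cur)) if forward else (
            e.source for e in graph.in_edges(cur))
        for n in nxt:
            if n not in seen:
                seen.add(n)
                stack.append(n)
    return seen


def match_parallel_join(graph: ProcessGraph, split_id: str) -> Optional[str]:
    """Find the parallel join matching ``split_id``, or None if unbalanced.

    Each branch is walked with a nesting depth counter; the first parallel
    join met at depth zero must be the same for every branch.
    """
    joins = set()
    for edge in graph.out_edges(split_id):
        cur, depth, hops = edge.target, 0, 0
        while True:
            hops += 1
            if hops > len(graph.edges) + 2:  # cycle guard
                return None
            kind = graph.kind_of(cur) if cur in graph.node_ids() else None
            if kind is None or kind == "end":
                return None
            if kind == PARALLEL_SPLIT:
                depth += 1
            elif kind == PARALLEL_JOIN:
                if depth == 0:
                    joins.add(cur)
                    break
                depth -= 1
            outs = graph.out_edges(cur)
            if len(outs) != 1 and kind not in (PARALLEL_SPLIT, EXCLUSIVE_SPLIT):
                return None
            if not outs:
                return None
            # through nested splits, follow the first branch far enough to
            # hit their join; for matching purposes any branch suffices
            cur = outs[0].target
    return joins.pop() if len(joins) == 1 else None


def match_exclusive_join(graph: ProcessGraph, split_id: str) -> Optional[str]:
    """Find the exclusive join where the split's branches reconverge."""
    joins = set()
    for edge in graph.out_edges(split_id):
        cur, depth, hops = edge.target, 0, 0
        while True:
            hops += 1
            if hops > len(graph.edges) + 2:
                return None
            kind = graph.kind_of(cur) if cur in graph.node_ids() else None
            if kind is None or kind == "end":
                return None
            if kind == EXCLUSIVE_SPLIT:
                depth += 1
            elif kind == EXCLUSIVE_JOIN:
                if depth == 0:
                    joins.add(cur)
                    break
                depth -= 1
            outs = graph.out_edges(cur)
            if not outs:
                return None
            cur = outs[0].target
    return joins.pop() if len(joins) == 1 else None


def validate_process(graph: ProcessGraph) -> list[str]:
    """Check all structural invariants; return violation records (empty = valid).

    Violations are strings of the form ``"<rule>: <node-or-detail>"``,
    deterministically ordered.  Nothing is raised: violations are data.
    """
    v: list[str] = []
    ids = graph.node_ids()

    if graph.start_id in graph.tasks or graph.start_id in graph.gateways:
        v.append(f"start_conflict: {graph.start_id}")
    if graph.end_id in graph.tasks or graph.end_id in graph.gateways:
        v.append(f"end_conflict: {graph.end_id}")

    for e in graph.edges:
        for endpoint in (e.source, e.target):
            if endpoint not in ids:
                v.append(f"dangling_edge: {e.source}->{e.target}")
                break

    fwd = _reachable(graph, graph.start_id, forward=True)
    bwd = _reachable(graph, graph.end_id, forward=False)
    for nid in sorted(ids - {graph.start_id, graph.end_id}):
        if nid not in fwd:
            v.append(f"unreachable: {nid}")
        if nid not in bwd:
            v.append(f"not_coreachable: {nid}")

    for gid in sorted(graph.gateways):
        if graph.gateways[gid].kind == PARALLEL_SPLIT:
            if match_parallel_join(graph, gid) is None:
                v.append(f"unbalanced_parallel: {gid}")

    attachable_types = {
        d.resource_type_id
        for t in graph.tasks.values()
        for d in t.demands
        if d.action == "attach"
    }
    for tid in sorted(graph.tasks):
        t = graph.tasks[tid]
        if t.default_duration_min < 0:
            v.append(f"negative_duration: {tid}")
        for g, dur in sorted(t.group_duration_overrides.items()):
            if dur < 0:
                v.append(f"negative_override: {tid}/{g}")
        for d in t.demands:
            if d.hold_mode == "sub_interval":
                off, length = d.sub_interval
                if off < 0 or length < 0 or off + length > t.default_duration_min:
                    v.append(f"sub_interval_out_of_range: {tid}/{d.resource_type_id}")
            if d.action == "detach" and d.resource_type_id not in attachable_types:
                v.append(f"detach_without_attach: {tid}/{d.resource_type_id}")

    for split_id in sorted(graph.redundant_groups):
        if split_id not in graph.gateways or graph.gateways[split_id].kind != EXCLUSIVE_SPLIT:
            v.append(f"redundant_group_not_exclusive_split: {split_id}")
            continue
        labels = {e.label for e in graph.out_edges(split_id)}
        for branch in graph.redundant_groups[split_id]:
            if branch not in labels:
                v.append(f"redundant_branch_missing: {split_id}/{branch}")

    return v


# ---------------------------------------------------------------------------
# Branch resolution & nominal path duration
# ---------------------------------------------------------------------------

def resolve_branch(
    graph: ProcessGraph,
    split_id: str,
    group_id: Optional[str],
    branch_choices: Optional[Mapping[str, str]] = None,
    branch_labels: Optional[Mapping[str, str]] = None,
) -> Edge:
    """Pick the outgoing edge of an exclusive split for a patient group.

    Resolution order: an explicit ``branch_choices`` entry, then the
    group's configured ``branch_labels``, then an edge whose label equals
    the group id, then the unlabeled default edge.
    """
    outs = graph.out_edges(split_id)
    wanted = None
    if branch_choices and split_id in branch_choices:
        wanted = branch_choices[split_id]
    elif branch_labels and split_id in branch_labels:
        wanted = branch_labels[split_id]
    if wanted is not None:
        for e in outs:
            if e.label == wanted:
                return e
        raise UnresolvedBranch(f"split {split_id}: no branch labeled {wanted!r}")
    for e in outs:
        if e.label == group_id:
            return e
    defaults = [e for e in outs if e.label is None]
    if len(defaults) == 1:
        return defaults[0]
    raise UnresolvedBranch(f"split {split_id}: no choice for group {group_id!r}")


def _walk_nominal(graph, node_id, loc, group_id, choices, labels, hospital, stop_at):
    """Sum effective durations + transit along a path; returns (minutes, loc, node)."""
    from .hospital import transit_time  # local import to avoid cycle

    total = 0.0
    cur = node_id
    guard = 0
    while True:
        guard += 1
        if guard > 10 * (len(graph.edges) + 2):
            raise MalformedProcess("cycle detected during nominal walk")
        if cur == stop_at or cur == graph.end_id:
            return total, loc, cur
        kind = graph.kind_of(cur)
        if kind == "start" or kind == EXCLUSIVE_JOIN:
            cur = graph.out_edges(cur)[0].target
        elif kind == "task":
            t = graph.tasks[cur]
            if loc is not None and t.area_id and t.area_id != loc:
                total += transit_time(hospital, loc, t.area_id)
            if t.area_id:
                loc = t.area_id
            total += t.duration_for(group_id)
            cur = graph.out_edges(cur)[0].target
        elif kind == EXCLUSIVE_SPLIT:
            if cur in graph.redundant_groups and not (choices and cur in choices):
                # redundant split without an explicit choice: take the branch
                # with the smallest nominal sum from here (ties: declaration
                # order), mirroring the engine's chooser on an idle hospital
                best = None
                for label in graph.redundant_groups[cur]:
                    mins = branch_nominal_sum(graph, cur, label, group_id, hospital, loc)
                    if best is None or mins < best[0]:
                        best = (mins, label)
                edge = resolve_branch(graph, cur, group_id, {cur: best[1]})
            else:
                edge = resolve_branch(graph, cur, group_id, choices, labels)
            cur = edge.target
        elif kind == PARALLEL_SPLIT:
            join = match_parallel_join(graph, cur)
            if join is None:
                raise MalformedProcess(f"unbalanced parallel split {cur}")
            best = None  # (minutes, branch_index, loc)
            for idx, e in enumerate(graph.out_edges(cur)):
                mins, bloc, _ = _walk_nominal(
                    graph, e.target, loc, group_id, choices, labels, hospital, join)
                if best is None or mins > best[0]:
                    best = (mins, idx, bloc)
            total += best[0]
            loc = best[2]
            cur = graph.out_edges(join)[0].target
        elif kind == PARALLEL_JOIN:
            # reached only when stop_at bypassed it; treat as pass-through
            cur = graph.out_edges(cur)[0].target
        else:  # pragma: no cover - defensive
            raise MalformedProcess(f"unexpected node kind {kind} at {cur}")


def nominal_path_duration(
    graph: ProcessGraph,
    group_id: Optional[str],
    hospital,
    branch_choices: Optional[Mapping[str, str]] = None,
    branch_labels: Optional[Mapping[str, str]] = None,
) -> float:
    """Undelayed processing time for one patient of ``group_id``.

    Sums effective task durations (group override else default) plus
    inter-area transit along the chosen path; a parallel block contributes
    the maximum over its branches.  No queueing, no modifiers.  The patient
    is assumed to appear in the area of the first task on its path.
    """
    total, _, _ = _walk_nominal(
        graph, graph.start_id, None, group_id, branch_choices, branch_labels,
        hospital, stop_at=None)
    return total


def branch_nominal_sum(graph, split_id, label, group_id, hospital, entry_loc):
    """Nominal minutes of one branch of an exclusive split (up to its join)."""
    join = match_exclusive_join(graph, split_id)
    target = None
    for e in graph.out_edges(split_id):
        if e.label == label:
            target = e.target
    if target is None:
        raise UnresolvedBranch(f"split {split_id}: no branch labeled {label!r}")
    stop = join if join is not None else graph.end_id
    mins, _, _ = _walk_nominal(graph, target, entry_loc, group_id, None, None, hospital, stop)
    return mins


def default_branch_choices(graph, group, hospital) -> dict[str, str]:
    """Resolve every exclusive split for a group the way the engine would
    with an idle hospital: redundant splits take the branch with the
    smallest nominal sum (ties: first-declared), conditional splits take
    the group's label / default.

    Used as the closed-form counterpart to the runtime branch chooser when
    predicting single-patient completion times.
    """
    choices: dict[str, str] = {}
    labels = getattr(group, "branch_labels", None) or {}
    gid = getattr(group, "id", group if isinstance(group, str) else None)
    for split_id in sorted(g for g, gw in graph.gateways.items()
                           if gw.kind == EXCLUSIVE_SPLIT):
        if split_id in graph.redundant_groups:
            best = None
            for label in graph.redundant_groups[split_id]:
                mins = branch_nominal_sum(graph, split_id, label, gid, hospital, None)
                if best is None or mins < best[0]:
                    best = (mins, label)
            choices[split_id] = best[1]
        else:
            edge = resolve_branch(graph, split_id, gid, None, labels)
            if edge.label is not None:
                choices[split_id] = edge.label
    return choices
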