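"""Synthetic fixtures: an emergency-trauma-room bundle and test substrates.

The real hospital process this package was motivated by (a 26-task
emergency trauma room pathway spanning ambulance, trauma room, CT,
operating room and intensive care, parameterized from trauma-registry
timestamps) is not public.  This module therefore generates a SYNTHETIC
stand-in with the same structure — 26 tasks, 5 areas, 6 injury groups,
the documented staff roster and device inventory — whose durations are
drawn once from documented uniform ranges and frozen by seed.  Numeric
agreement with any real hospital is not claimed; the bundle exists so
every other module is testable and so scenario sweeps show the
qualitative shapes the method produces (monotone outage response,
efficiency saturation at the single CT scanner, overload delay).

Also provided: a tiny two-task fixture for unit tests, a random
small-process generator for oracle-equivalence testing, and a synthetic
trauma-registry-like cohort (AIS profiles plus per-action timestamps)
with an aggregation helper emulating the duration-estimation path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import ScenarioSpec
from .hospital import (
    Area,
    HospitalState,
    ResourceInstance,
    ResourceType,
    TransitMatrix,
)
from .patients import AISProfile, InjuryGroup, generate_patients
from .process import ProcessGraph, parse_bpmn


@dataclass
class FixtureBundle:
    """A coherent process + hospital + groups + named ready-to-run scenarios."""

    graph: ProcessGraph
    hospital: HospitalState
    groups: list[InjuryGroup]
    scenarios: dict[str, ScenarioSpec] = field(default_factory=dict)
    task_meta: dict = field(default_factory=dict)


def _derive_seed(seed: int, k: int) -> int:
    return (seed * 1000003 + k) % (2 ** 31)


def _bpmn(elements: list[str], flows: list[tuple[str, str, str | None]]) -> str:
    """Assemble a BPMN document from prepared element tags and flows."""
    lines = ['<?xml version="1.0" encoding="UTF-8"?>',
             '<definitions xmlns="http://www.omg.org/spec/BPMN/20100524/MODEL">',
             '  <process id="process_1">']
    lines += [f"    {el}" for el in elements]
    for i, (src, dst, label) in enumerate(flows):
        name = f' name="{label}"' if label else ""
        lines.append(f'    <sequenceFlow id="f{i}" sourceRef="{src}" '
                     f'targetRef="{dst}"{name}/>')
    lines += ["  </process>", "</definitions>"]
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Minimal fixture
# ---------------------------------------------------------------------------

def build_minimal_fixture() -> FixtureBundle:
    """One area, two sequential tasks, one portable and one stationary type."""
    doc = _bpmn(
        ['<startEvent id="start"/>', '<task id="T1" name="triage"/>',
         '<task id="T2" name="scan"/>', '<endEvent id="end"/>'],
        [("start", "T1", None), ("T1", "T2", None), ("T2", "end", None)])
    meta = {
        "T1": {"area": "er", "duration_min": 5.0,
               "demands": [{"type": "nurse"}]},
        "T2": {"area": "er", "duration_min": 7.0,
               "demands": [{"type": "nurse"}, {"type": "scanner"}]},
    }
    graph = parse_bpmn(doc, meta)
    hospital = HospitalState(
        areas={"er": Area(id="er", name="emergency room")},
        transit=TransitMatrix(),
        types={
            "nurse": ResourceType(id="nurse", category="staff"),
            "scanner": ResourceType(id="scanner", mobility="stationary"),
        },
        instances={
            "nurse_1": ResourceInstance(id="nurse_1", type_id="nurse", home_area="er"),
            "nurse_2": ResourceInstance(id="nurse_2", type_id="nurse", home_area="er"),
            "scanner_1": ResourceInstance(id="scanner_1", type_id="scanner", home_area="er"),
        },
    )
    group = InjuryGroup(id="g_min", ais_signature=AISProfile((0,) * 9), priority=1)
    cohort = generate_patients([group], {"g_min": 1}, [(0.0, 0.0, 1)], seed=0)
    spec = ScenarioSpec(graph=graph, hospital=hospital, groups=[group],
                        cohort=cohort, horizon_min=500.0)
    return FixtureBundle(graph=graph, hospital=hospital, groups=[group],
                         scenarios={"baseline": spec}, task_meta=meta)


# ---------------------------------------------------------------------------
# ETR fixture
# ---------------------------------------------------------------------------

# (id, name, area, (lo, hi) duration range, demands, ttd_delta, ttr_delta)
#
# Three phases mirroring standard trauma-room practice: a serial first
# survey (airway/breathing/circulation), then the team splits up and works
# in parallel (bleeding control, imaging, access/second survey), then CT
# and disposition.  The trauma leader coordinates throughout and is the
# scarce skill under load.
_ETR_TASKS = [
    ("t01", "handover", "ambulance", (6, 9),
     [{"type": "paramedic", "count": 2}], 0, 0),
    ("t02", "team_briefing", "etr", (2, 3), [{"type": "trauma_leader"}], 0, 0),
    ("t03", "airway_check", "etr", (1, 3), [{"type": "senior_anesthetist"}], 0, 0),
    ("t04", "intubation", "etr", (3, 5),
     [{"type": "senior_anesthetist"}, {"type": "anesthetic_nurse"},
      {"type": "ventilator", "action": "attach"}], 10, 20),
    ("t05", "circulation_check", "etr", (2, 3), [{"type": "trauma_leader"}], 0, 0),
    # parallel branch 1: bleeding control (with conditional chest drain)
    ("t06", "attach_monitoring", "etr", (1, 2),
     [{"type": "surgical_nurse"}, {"type": "monitor", "action": "attach"}], 0, 0),
    ("t07", "stop_bleeding", "etr", (8, 10),
     [{"type": "trauma_leader"}, {"type": "junior_surgeon"},
      {"type": "surgical_nurse"}], 30, 30),
    ("t08", "chest_drain", "etr", (4, 6),
     [{"type": "trauma_leader"}, {"type": "surgical_nurse"}], 15, 15),
    # parallel branch 2: imaging
    ("t12", "xray_thorax", "etr", (2, 4),
     [{"type": "radiographer"}, {"type": "xray_portable"}], 0, 0),
    ("t13", "xray_pelvis", "etr", (2, 3),
     [{"type": "radiographer"}, {"type": "xray_portable"}], 0, 0),
    ("t14", "fast_ultrasound", "etr", (3, 5),
     [{"type": "junior_surgeon"}, {"type": "ultrasound"}], 0, 0),
    # parallel branch 3: access, medication, second survey
    ("t09", "iv_access", "etr", (1, 3),
     [{"type": "anesthetic_nurse"},
      {"type": "infusion_pump", "action": "attach"}], 0, 0),
    ("t10", "medication", "etr", (1, 2), [{"type": "senior_anesthetist"}], 0, 0),
    ("t11", "volume_therapy", "etr", (2, 5), [{"type": "anesthetic_nurse"}], 20, 20),
    ("t15", "blood_analysis", "etr", (2, 4),
     [{"type": "surgical_nurse"}, {"type": "blood_analyzer"}], 0, 0),
    ("t16", "second_survey", "etr", (6, 8),
     [{"type": "trauma_leader"}, {"type": "junior_surgeon"}], 0, 0),
    ("t17", "catheter", "etr", (2, 4), [{"type": "surgical_nurse"}], 0, 0),
    # after the join
    ("t18", "image_review", "etr", (2, 3),
     [{"type": "trauma_leader"}, {"type": "radiologist"}], 0, 0),
    ("t19", "ct_transfer_prep", "etr", (1, 2), [{"type": "surgical_nurse"}], 0, 0),
    ("t20", "ct_scan", "ct", (14, 16), [{"type": "ct_scanner"}], 0, 0),
    ("t21", "ct_image_review", "ct", (2, 3), [{"type": "radiologist"}], 0, 0),
    ("t22", "or_prep", "or", (2, 4), [{"type": "or_team"}], 0, 0),
    ("t23", "surgery", "or", (14, 18),
     [{"type": "or_team", "count": 2}, {"type": "or_table"},
      {"type": "ventilator", "action": "detach"},
      {"type": "monitor", "action": "detach"},
      {"type": "infusion_pump", "action": "detach"}], 60, 60),
    ("t24", "or_handoff", "or", (1, 3), [{"type": "or_team"}], 0, 0),
    ("t25", "icu_admission", "icu", (2, 4), [{"type": "icu_nurse"}], 0, 0),
    ("t26", "icu_stabilization", "icu", (14, 18),
     [{"type": "icu_nurse", "count": 2}, {"type": "icu_bed"},
      {"type": "ventilator", "action": "detach"},
      {"type": "monitor", "action": "detach"},
      {"type": "infusion_pump", "action": "detach"}], 60, 60),
]

#: tasks whose duration is overridden per group by a severity factor.
#: Trauma-room survey and the whole-body CT protocol are standardized and
#: take similar time for every major-trauma patient; severity shows up in
#: the definitive care (surgery / ICU stabilization).
_OVERRIDDEN = ("t23", "t26")

_GROUP_DEFS = [
    # (id, AIS regions, priority, factor, ttd range, ttr range, chest drain?)
    ("g1_polytrauma", {"head": 4, "thorax": 4, "abdomen": 3, "spine": 2, "external": 1},
     6, 1.30, (90, 150), (360, 480), True),
    ("g2_head", {"head": 5, "neck": 2}, 5, 1.20, (120, 180), (400, 520), False),
    ("g3_thorax", {"thorax": 4, "upper_extremity": 2}, 4, 1.15, (150, 240),
     (420, 540), True),
    ("g4_abdomen", {"abdomen": 3, "lower_extremity": 2}, 3, 1.00, (180, 270),
     (480, 600), False),
    ("g5_fracture", {"upper_extremity": 3, "lower_extremity": 3}, 2, 0.85,
     (240, 360), None, False),
    ("g6_minor", {"external": 2, "face": 1}, 1, 0.70, None, None, False),
]

_ETR_STAFF = {
    "paramedic": ("ambulance", 2), "trauma_leader": ("etr", 1),
    "junior_surgeon": ("etr", 2), "senior_anesthetist": ("etr", 1),
    "surgical_nurse": ("etr", 2), "anesthetic_nurse": ("etr", 1),
    "radiographer": ("etr", 1), "radiologist": ("etr", 1),
    "or_team": ("or", 4), "icu_nurse": ("icu", 4),
}

_ETR_DEVICES = {
    # type: (area, count, mobility, attachable)
    "xray_portable": ("etr", 1, "portable", False),
    "ultrasound": ("etr", 1, "portable", False),
    "defibrillator": ("etr", 1, "portable", False),
    "blood_analyzer": ("etr", 1, "stationary", False),
    "monitor": ("etr", 8, "portable", True),
    "ventilator": ("etr", 8, "portable", True),
    "infusion_pump": ("etr", 8, "portable", True),
    "ct_scanner": ("ct", 1, "stationary", False),
    "or_table": ("or", 2, "stationary", False),
    "icu_bed": ("icu", 4, "stationary", False),
}

_ETR_TRANSIT = {
    ("ambulance", "etr"): 2, ("etr", "ct"): 1, ("etr", "or"): 4,
    ("etr", "icu"): 5, ("ct", "or"): 3, ("ct", "icu"): 4,
    ("or", "icu"): 3, ("ambulance", "ct"): 3, ("ambulance", "or"): 5,
    ("ambulance", "icu"): 6,
}


def _etr_bpmn() -> str:
    elements = ['<startEvent id="start"/>']
    for tid, name, *_ in _ETR_TASKS:
        elements.append(f'<task id="{tid}" name="{name}"/>')
    elements += [
        '<exclusiveGateway id="chest_split"/>', '<exclusiveGateway id="chest_join"/>',
        '<parallelGateway id="team_split"/>', '<parallelGateway id="team_join"/>',
        '<exclusiveGateway id="dispo_split"/>', '<exclusiveGateway id="dispo_join"/>',
        '<endEvent id="end"/>',
    ]
    flows = [
        # first survey: serial stabilization
        ("start", "t01", None), ("t01", "t02", None), ("t02", "t03", None),
        ("t03", "t04", None), ("t04", "t05", None), ("t05", "team_split", None),
        # branch 1: bleeding control, chest drain for thorax-severe groups
        ("team_split", "t06", None), ("t06", "t07", None),
        ("t07", "chest_split", None),
        ("chest_split", "t08", "chest_drain"), ("t08", "chest_join", None),
        ("chest_split", "chest_join", None), ("chest_join", "team_join", None),
        # branch 2: imaging
        ("team_split", "t12", None), ("t12", "t13", None), ("t13", "t14", None),
        ("t14", "team_join", None),
        # branch 3: access, medication, second survey
        ("team_split", "t09", None), ("t09", "t10", None), ("t10", "t11", None),
        ("t11", "t15", None), ("t15", "t16", None), ("t16", "t17", None),
        ("t17", "team_join", None),
        # review, CT, disposition
        ("team_join", "t18", None), ("t18", "t19", None), ("t19", "t20", None),
        ("t20", "t21", None), ("t21", "dispo_split", None),
        ("dispo_split", "t22", "or_path"), ("t22", "t23", None),
        ("t23", "t24", None), ("t24", "dispo_join", None),
        ("dispo_split", "t25", "icu_path"), ("t25", "t26", None),
        ("t26", "dispo_join", None),
        ("dispo_join", "end", None),
    ]
    return _bpmn(elements, flows)


def build_etr_fixture(seed: int = 0) -> FixtureBundle:
    """Build the synthetic 26-task / 5-area / 6-group trauma-room bundle.

    Durations are drawn once per task, uniformly from the documented range,
    with one ``numpy`` stream seeded by ``seed`` (so the same seed always
    yields the identical bundle).  Injury-group overrides multiply the drawn
    duration of the clinically severity-sensitive tasks by the group's
    factor.  The disposition split (operating room vs intensive care) is
    marked redundant; patients take whichever is estimated faster.
    """
    rng = np.random.default_rng(_derive_seed(seed, 0))
    groups = []
    for gid, ais, prio, factor, ttd, ttr, chest in _GROUP_DEFS:
        groups.append(InjuryGroup(
            id=gid,
            ais_signature=AISProfile.from_mapping(ais),
            priority=prio,
            ttd_range_min=tuple(map(float, ttd)) if ttd else None,
            ttr_range_min=tuple(map(float, ttr)) if ttr else None,
            branch_labels={"chest_split": "chest_drain"} if chest else {},
        ))
    factors = {gid: factor for gid, _, _, factor, _, _, _ in _GROUP_DEFS}

    task_meta: dict = {}
    for tid, name, area, (lo, hi), demands, ttd_d, ttr_d in _ETR_TASKS:
        dur = round(float(rng.uniform(lo, hi)), 1)
        meta = {"name": name, "area": area, "duration_min": dur,
                "demands": demands, "ttd_delta_min": float(ttd_d),
                "ttr_delta_min": float(ttr_d)}
        if tid in _OVERRIDDEN:
            meta["overrides"] = {g: round(dur * f, 1) for g, f in factors.items()}
        task_meta[tid] = meta

    graph = parse_bpmn(_etr_bpmn(), task_meta,
                       redundant_groups={"dispo_split": ["or_path", "icu_path"]})

    areas = {a: Area(id=a, name=a) for a in
             ("ambulance", "etr", "ct", "or", "icu")}
    areas["etr"].min_stock = {"monitor": 1, "infusion_pump": 1}
    types: dict[str, ResourceType] = {}
    instances: dict[str, ResourceInstance] = {}
    for t, (area, n) in _ETR_STAFF.items():
        types[t] = ResourceType(id=t, category="staff", skill_class=t)
        for i in range(n):
            iid = f"{t}_{i + 1}"
            instances[iid] = ResourceInstance(id=iid, type_id=t, home_area=area)
    for t, (area, n, mobility, attachable) in _ETR_DEVICES.items():
        types[t] = ResourceType(id=t, category="device", mobility=mobility,
                                attachable=attachable)
        for i in range(n):
            iid = f"{t}_{i + 1}"
            instances[iid] = ResourceInstance(id=iid, type_id=t, home_area=area)

    hospital = HospitalState(
        areas=areas,
        transit=TransitMatrix.from_symmetric(
            {k: float(v) for k, v in _ETR_TRANSIT.items()}),
        types=types,
        instances=instances,
        avg_travel_min=20.0,
    )

    bundle = FixtureBundle(graph=graph, hospital=hospital, groups=groups,
                           task_meta=task_meta)
    standard = build_standard_scenario(bundle, _derive_seed(seed, 1))
    bundle.scenarios = {
        "baseline": standard,
        "outage": build_standard_scenario(bundle, _derive_seed(seed, 1)),
        "efficiency": build_standard_scenario(bundle, _derive_seed(seed, 1)),
        "mci": build_mci_scenario(bundle, _derive_seed(seed, 2)),
    }
    return bundle


def build_standard_scenario(bundle: FixtureBundle, seed: int) -> ScenarioSpec:
    """Twelve patients, two per group, one arriving roughly every three hours.

    The spacing emulates a normal day's trauma-room census: each patient
    arrives in a 30-minute window at 180-minute intervals, so successive
    patients never overlap and the undisturbed run has zero delay.  This
    is the substrate for the outage and efficiency sweeps, where
    disruption — not overload — should drive the response.
    """
    counts = {g.id: 2 for g in bundle.groups}
    windows = [(180.0 * i, 180.0 * i + 30.0, 1) for i in range(12)]
    cohort = generate_patients(bundle.groups, counts, windows, seed)
    return ScenarioSpec(graph=bundle.graph, hospital=bundle.hospital,
                        groups=bundle.groups, cohort=cohort, seed=seed,
                        horizon_min=4000.0)


def build_mci_scenario(bundle: FixtureBundle, seed: int) -> ScenarioSpec:
    """Mass-casualty overload: two batches of six, minutes [3,15] and [39,89].

    Twelve patients, two per group; the round-robin generation order puts
    one patient of each group in each batch.  Within each batch the drawn
    arrival times are assigned in triage-priority order — rescue services
    deliver the most critical patients first.
    """
    counts = {g.id: 2 for g in bundle.groups}
    windows = [(3.0, 15.0, 6), (39.0, 89.0, 6)]
    cohort = generate_patients(bundle.groups, counts, windows, seed)
    prio = {g.id: g.priority for g in bundle.groups}
    for lo, hi, _ in windows:
        batch = [p for p in cohort if lo <= p.t_start_min <= hi]
        times = sorted(p.t_start_min for p in batch)
        batch.sort(key=lambda p: (-prio[p.group_id], p.id))
        for p, t in zip(batch, times):
            p.t_start_min = t
    return ScenarioSpec(graph=bundle.graph, hospital=bundle.hospital,
                        groups=bundle.groups, cohort=cohort, seed=seed,
                        horizon_min=4000.0)


# ---------------------------------------------------------------------------
# Random small processes (oracle substrate)
# ---------------------------------------------------------------------------

def build_random_process(seed: int, max_tasks: int = 8,
                         max_parallel_blocks: int = 2,
                         n_areas: int = 2) -> ScenarioSpec:
    """A random small process with ample resources and one patient.

    Structure: a chain of blocks, each a single task, a two-branch parallel
    block or a two-branch redundant exclusive block; at most ``max_tasks``
    tasks overall.  Every task's demands are amply stocked in its own area,
    so a lone patient is never delayed by allocation — simulated completion
    must equal the closed-form nominal path duration.
    """
    rng = np.random.default_rng(seed)
    areas = [f"a{i}" for i in range(max(1, n_areas))]
    type_ids = ["staff_a", "staff_b", "dev_a"]

    elements = ['<startEvent id="start"/>', '<endEvent id="end"/>']
    flows: list[tuple[str, str, str | None]] = []
    task_meta: dict = {}
    redundant: dict[str, list[str]] = {}
    task_n = 0
    gw_n = 0

    def new_task() -> str:
        nonlocal task_n
        task_n += 1
        tid = f"rt{task_n}"
        elements.append(f'<task id="{tid}"/>')
        demands = [{"type": type_ids[int(rng.integers(0, len(type_ids)))]}]
        task_meta[tid] = {
            "area": areas[int(rng.integers(0, len(areas)))],
            "duration_min": round(float(rng.uniform(1, 20)) * 2) / 2,
            "demands": demands,
        }
        return tid

    def chain(n: int) -> tuple[str, str]:
        first = prev = new_task()
        for _ in range(n - 1):
            nxt = new_task()
            flows.append((prev, nxt, None))
            prev = nxt
        return first, prev

    cursor = "start"
    parallel_used = 0
    while task_n < max_tasks - 1:
        room = max_tasks - task_n
        choices = ["task"]
        if room >= 3 and parallel_used < max_parallel_blocks:
            choices.append("parallel")
        if room >= 2:
            choices.append("redundant")
        kind = choices[int(rng.integers(0, len(choices)))]
        if kind == "task":
            tid = new_task()
            flows.append((cursor, tid, None))
            cursor = tid
        elif kind == "parallel":
            parallel_used += 1
            gw_n += 1
            sp, jn = f"ps{gw_n}", f"pj{gw_n}"
            elements += [f'<parallelGateway id="{sp}"/>',
                         f'<parallelGateway id="{jn}"/>']
            flows.append((cursor, sp, None))
            for _ in range(2):
                n = int(rng.integers(1, min(3, max(2, room - 1))))
                first, last = chain(n)
                flows += [(sp, first, None), (last, jn, None)]
            cursor = jn
        else:  # redundant exclusive block
            gw_n += 1
            sp, jn = f"xs{gw_n}", f"xj{gw_n}"
            elements += [f'<exclusiveGateway id="{sp}"/>',
                         f'<exclusiveGateway id="{jn}"/>']
            flows.append((cursor, sp, None))
            labels = []
            for b in range(2):
                n = int(rng.integers(1, min(3, max(2, room - 1))))
                first, last = chain(n)
                label = f"{sp}_b{b}"
                labels.append(label)
                flows += [(sp, first, label), (last, jn, None)]
            redundant[sp] = labels
            cursor = jn
        if task_n >= max_tasks - 1 or rng.uniform() < 0.2:
            break
    if task_n == 0:
        tid = new_task()
        flows.append((cursor, tid, None))
        cursor = tid
    flows.append((cursor, "end", None))

    graph = parse_bpmn(_bpmn(elements, flows), task_meta,
                       redundant_groups=redundant)
    types = {
        "staff_a": ResourceType(id="staff_a", category="staff"),
        "staff_b": ResourceType(id="staff_b", category="staff"),
        "dev_a": ResourceType(id="dev_a", category="device"),
    }
    instances = {}
    for a in areas:
        for t in type_ids:
            for i in range(4):
                iid = f"{t}_{a}_{i}"
                instances[iid] = ResourceInstance(id=iid, type_id=t, home_area=a)
    transit = TransitMatrix.from_symmetric({
        (a, b): float(rng.integers(1, 6))
        for i, a in enumerate(areas) for b in areas[i + 1:]})
    hospital = HospitalState(
        areas={a: Area(id=a) for a in areas},
        transit=transit,
        types=types,
        instances=instances,
    )
    group = InjuryGroup(id="g_rand", ais_signature=AISProfile((0,) * 9), priority=1)
    cohort = generate_patients([group], {"g_rand": 1}, [(0.0, 0.0, 1)],
                               seed=_derive_seed(seed, 7))
    return ScenarioSpec(graph=graph, hospital=hospital, groups=[group],
                        cohort=cohort, seed=seed, horizon_min=10000.0)


# ---------------------------------------------------------------------------
# Synthetic trauma-registry-like cohort
# ---------------------------------------------------------------------------

def trdgu_true_means(groups: list[InjuryGroup]) -> dict[str, dict[str, float]]:
    """Deterministic per-group true mean action durations (minutes)."""
    means = {}
    for i, g in enumerate(groups):
        means[g.id] = {
            "arrival_to_xray": 10.0 + 2.0 * i,
            "xray_to_ct": 15.0 + 3.0 * i,
            "ct_to_surgery": 25.0 + 4.0 * i,
        }
    return means


def synthetic_trdgu_cohort(n: int, groups: list[InjuryGroup], seed: int) -> pd.DataFrame:
    """Generate ``n`` registry-like records: AIS profile + action timestamps.

    Each record carries one group's exact AIS signature (so it is
    classifiable) and monotone timestamps arrival ≤ x-ray ≤ CT ≤ surgery,
    with gamma-jittered inter-action durations around the group's true
    mean (shape 9, hence relative SD 1/3).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    means = trdgu_true_means(groups)
    shape = 9.0
    rows = []
    from .patients import AIS_REGIONS
    for i in range(n):
        g = groups[int(rng.integers(0, len(groups)))]
        arrival = float(rng.uniform(0, 24 * 60))
        m = means[g.id]
        d1 = float(rng.gamma(shape, m["arrival_to_xray"] / shape))
        d2 = float(rng.gamma(shape, m["xray_to_ct"] / shape))
        d3 = float(rng.gamma(shape, m["ct_to_surgery"] / shape))
        row = {"record_id": f"R{i + 1:04d}", "group_id": g.id,
               "t_arrival_min": arrival,
               "t_xray_min": arrival + d1,
               "t_ct_min": arrival + d1 + d2,
               "t_surgery_min": arrival + d1 + d2 + d3}
        for region, sev in zip(AIS_REGIONS, g.ais_signature.severities):
            row[f"ais_{region}"] = sev
        rows.append(row)
    return pd.DataFrame(rows)


def aggregate_action_durations(records: pd.DataFrame) -> pd.DataFrame:
    """Mean per-action duration per group from a registry-like table.

    Emulates the duration-estimation path: timestamps in, average minutes
    per action per injury group out.
    """
    out = records.copy()
    out["arrival_to_xray"] = out["t_xray_min"] - out["t_arrival_min"]
    out["xray_to_ct"] = out["t_ct_min"] - out["t_xray_min"]
    out["ct_to_surgery"] = out["t_surgery_min"] - out["t_ct_min"]
    return out.groupby("group_id")[
        ["arrival_to_xray", "xray_to_ct", "ct_to_surgery"]].mean()
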