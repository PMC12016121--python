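"""Reading and writing scenarios: BPMN + YAML config + cohort CSV.

One scenario on disk is three text files:

``process.bpmn``
    the process structure (events, tasks, gateways, labelled flows);
``config.yaml``
    hospital (areas, transit, resource types, instances), task metadata
    keyed by BPMN task id, injury groups, redundancy marks, modifiers,
    seed and horizon;
``cohort.csv``
    one row per patient: ``patient_id, group_id, t_start_min, ttd_min,
    ttr_min, ais_head .. ais_external``.

``save_scenario``/``load_scenario`` round-trip losslessly.  The loader
collects *all* cross-reference problems and raises a single
:class:`~wardflow.errors.ConfigError`, so a user sees every broken id at
once rather than the first.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .engine import ScenarioSpec
from .errors import ConfigError
from .fixtures import build_etr_fixture, build_minimal_fixture
from .hospital import (
    Area,
    HospitalState,
    Modifier,
    ResourceInstance,
    ResourceType,
    TransitMatrix,
)
from .patients import AIS_REGIONS, AISProfile, InjuryGroup, Patient
from .process import ProcessGraph, parse_bpmn, to_bpmn


@dataclass
class RunConfig:
    """What a run needs: either three file paths or a bundled fixture name."""

    bpmn_path: Optional[str] = None
    config_path: Optional[str] = None
    cohort_path: Optional[str] = None
    fixture: Optional[str] = None  # "minimal" | "etr"
    scenario: str = "baseline"
    seed: int = 0
    horizon_min: Optional[float] = None
    out_dir: str = "results"

    def __post_init__(self):
        files = self.bpmn_path is not None and self.config_path is not None
        if files == (self.fixture is not None):
            raise ConfigError(
                ["exactly one of {bpmn+config paths, fixture name} must be given"])


# ---------------------------------------------------------------------------
# Serialization helpers
# ---------------------------------------------------------------------------

def _demand_to_dict(d) -> dict:
    out = {"type": d.resource_type_id}
    if d.count != 1:
        out["count"] = d.count
    if d.action != "use":
        out["action"] = d.action
    if d.hold_mode == "sub_interval":
        out["hold"] = "sub_interval"
        out["sub_interval"] = list(d.sub_interval)
    return out


def task_meta_from_graph(graph: ProcessGraph) -> dict:
    meta = {}
    for tid in sorted(graph.tasks):
        t = graph.tasks[tid]
        m: dict = {"area": t.area_id, "duration_min": t.default_duration_min}
        if t.name:
            m["name"] = t.name
        if t.demands:
            m["demands"] = [_demand_to_dict(d) for d in t.demands]
        if t.group_duration_overrides:
            m["overrides"] = dict(sorted(t.group_duration_overrides.items()))
        if t.ttd_delta_min:
            m["ttd_delta_min"] = t.ttd_delta_min
        if t.ttr_delta_min:
            m["ttr_delta_min"] = t.ttr_delta_min
        meta[tid] = m
    return meta


def hospital_to_dict(h: HospitalState) -> dict:
    return {
        "avg_travel_min": h.avg_travel_min,
        "areas": [
            {"id": a.id, "name": a.name, "active": a.active,
             "quarantined": a.quarantined, "on_call": a.on_call,
             "min_stock": dict(sorted(a.min_stock.items()))}
            for a in (h.areas[k] for k in sorted(h.areas))],
        "transit": [
            {"from": a, "to": b, "minutes": t}
            for (a, b), t in sorted(h.transit.minutes.items())],
        "resource_types": [
            {"id": t.id, "category": t.category, "mobility": t.mobility,
             "skill_class": t.skill_class, "attachable": t.attachable}
            for t in (h.types[k] for k in sorted(h.types))],
        "instances": [
            {"id": i.id, "type": i.type_id, "home_area": i.home_area,
             "efficiency_pct": i.efficiency_pct}
            for i in (h.instances[k] for k in sorted(h.instances))],
    }


def hospital_from_dict(d: dict, problems: list[str]) -> HospitalState:
    areas = {}
    for a in d.get("areas", []):
        areas[a["id"]] = Area(
            id=a["id"], name=a.get("name", ""), active=a.get("active", True),
            quarantined=a.get("quarantined", False), on_call=a.get("on_call", False),
            min_stock={k: int(v) for k, v in (a.get("min_stock") or {}).items()})
    transit = TransitMatrix(minutes={
        (e["from"], e["to"]): float(e["minutes"]) for e in d.get("transit", [])})
    types = {}
    for t in d.get("resource_types", []):
        try:
            types[t["id"]] = ResourceType(
                id=t["id"], category=t.get("category", "device"),
                mobility=t.get("mobility", "portable"),
                skill_class=t.get("skill_class"),
                attachable=t.get("attachable", False))
        except ValueError as exc:
            problems.append(f"resource_type {t.get('id')}: {exc}")
    instances = {}
    for i in d.get("instances", []):
        instances[i["id"]] = ResourceInstance(
            id=i["id"], type_id=i["type"], home_area=i["home_area"],
            efficiency_pct=float(i.get("efficiency_pct", 100.0)))
    return HospitalState(areas=areas, transit=transit, types=types,
                         instances=instances,
                         avg_travel_min=float(d.get("avg_travel_min", 0.0)))


def groups_to_list(groups: list[InjuryGroup]) -> list[dict]:
    return [
        {"id": g.id, "priority": g.priority,
         "ais": {r: s for r, s in g.ais_signature.as_mapping().items() if s},
         "ttd_range_min": list(g.ttd_range_min) if g.ttd_range_min else None,
         "ttr_range_min": list(g.ttr_range_min) if g.ttr_range_min else None,
         "branch_labels": dict(sorted(g.branch_labels.items()))}
        for g in groups]


def groups_from_list(items: list[dict], problems: list[str]) -> list[InjuryGroup]:
    groups = []
    for d in items:
        try:
            groups.append(InjuryGroup(
                id=d["id"],
                ais_signature=AISProfile.from_mapping(d.get("ais") or {}),
                priority=int(d.get("priority", 0)),
                ttd_range_min=tuple(d["ttd_range_min"]) if d.get("ttd_range_min") else None,
                ttr_range_min=tuple(d["ttr_range_min"]) if d.get("ttr_range_min") else None,
                branch_labels=dict(d.get("branch_labels") or {})))
        except (KeyError, ValueError) as exc:
            problems.append(f"group {d.get('id')}: {exc}")
    return groups


def modifiers_to_list(mods: list[Modifier]) -> list[dict]:
    return [
        {"at_min": m.at_min, "kind": m.kind,
         "target": list(m.target) if isinstance(m.target, tuple) else m.target,
         "value": m.value}
        for m in mods]


def modifiers_from_list(items: list[dict], problems: list[str]) -> list[Modifier]:
    mods = []
    for d in items:
        try:
            target = d["target"]
            if isinstance(target, list):
                target = tuple(target)
            mods.append(Modifier(at_min=float(d["at_min"]), kind=d["kind"],
                                 target=target,
                                 value=None if d.get("value") is None else float(d["value"])))
        except (KeyError, ValueError) as exc:
            problems.append(f"modifier {d}: {exc}")
    return mods


# ---------------------------------------------------------------------------
# Cohort CSV
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["patient_id", "group_id", "t_start_min", "ttd_min", "ttr_min"] + [
    f"ais_{r}" for r in AIS_REGIONS]


def cohort_to_frame(cohort: list[Patient]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        row = {"patient_id": p.id, "group_id": p.group_id,
               "t_start_min": p.t_start_min,
               "ttd_min": p.ttd_initial_min, "ttr_min": p.ttr_initial_min}
        sev = p.ais.severities if p.ais is not None else (0,) * 9
        for r, s in zip(AIS_REGIONS, sev):
            row[f"ais_{r}"] = s
        rows.append(row)
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def cohort_from_frame(df: pd.DataFrame) -> list[Patient]:
    cohort = []
    for _, row in df.iterrows():
        cohort.append(Patient(
            id=str(row["patient_id"]), group_id=str(row["group_id"]),
            t_start_min=float(row["t_start_min"]),
            ttd_initial_min=None if pd.isna(row["ttd_min"]) else float(row["ttd_min"]),
            ttr_initial_min=None if pd.isna(row["ttr_min"]) else float(row["ttr_min"]),
            ais=AISProfile(tuple(int(row[f"ais_{r}"]) for r in AIS_REGIONS))))
    return cohort


# ---------------------------------------------------------------------------
# Save / load
# ---------------------------------------------------------------------------

def save_scenario(spec: ScenarioSpec, directory: str | Path) -> dict[str, Path]:
    """Write process.bpmn, config.yaml and cohort.csv; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "bpmn": directory / "process.bpmn",
        "config": directory / "config.yaml",
        "cohort": directory / "cohort.csv",
    }
    paths["bpmn"].write_text(to_bpmn(spec.graph))
    config = {
        "seed": spec.seed,
        "horizon_min": spec.horizon_min,
        "hospital": hospital_to_dict(spec.hospital),
        "tasks": task_meta_from_graph(spec.graph),
        "redundant_groups": {k: list(v) for k, v in
                             sorted(spec.graph.redundant_groups.items())},
        "groups": groups_to_list(spec.groups),
        "modifiers": modifiers_to_list(spec.modifiers),
    }
    paths["config"].write_text(yaml.safe_dump(config, sort_keys=False))
    # %.17g round-trips IEEE doubles exactly
    frame = cohort_to_frame(spec.cohort)
    for col in ("t_start_min", "ttd_min", "ttr_min"):
        frame[col] = frame[col].astype(float)
    frame.to_csv(paths["cohort"], index=False, float_format="%.17g")
    return paths


def load_scenario_files(
    bpmn_path: str | Path,
    config_path: str | Path,
    cohort_path: Optional[str | Path] = None,
) -> ScenarioSpec:
    """Load and cross-validate a scenario; all problems reported together."""
    problems: list[str] = []
    config = yaml.safe_load(Path(config_path).read_text()) or {}
    hospital = hospital_from_dict(config.get("hospital") or {}, problems)
    groups = groups_from_list(config.get("groups") or [], problems)
    modifiers = modifiers_from_list(config.get("modifiers") or [], problems)
    try:
        graph = parse_bpmn(
            Path(bpmn_path).read_text(),
            config.get("tasks") or {},
            redundant_groups=config.get("redundant_groups") or {})
    except Exception as exc:
        raise ConfigError(problems + [f"bpmn: {exc}"]) from exc
    cohort: list[Patient] = []
    if cohort_path is not None:
        cohort = cohort_from_frame(
            pd.read_csv(cohort_path, float_precision="round_trip"))
    spec = ScenarioSpec(
        graph=graph, hospital=hospital, groups=groups, cohort=cohort,
        modifiers=modifiers, seed=int(config.get("seed", 0)),
        horizon_min=float(config.get("horizon_min", 1e6)))
    problems.extend(spec.validate())
    if problems:
        raise ConfigError(problems)
    return spec


def load_scenario(cfg: RunConfig) -> ScenarioSpec:
    """Resolve a :class:`RunConfig` to a validated :class:`ScenarioSpec`."""
    if cfg.fixture is not None:
        if cfg.fixture == "minimal":
            bundle = build_minimal_fixture()
        elif cfg.fixture == "etr":
            bundle = build_etr_fixture(cfg.seed)
        else:
            raise ConfigError([f"unknown fixture {cfg.fixture!r}"])
        if cfg.scenario not in bundle.scenarios:
            raise ConfigError(
                [f"fixture {cfg.fixture!r} has no scenario {cfg.scenario!r}; "
                 f"available: {sorted(bundle.scenarios)}"])
        spec = bundle.scenarios[cfg.scenario]
    else:
        spec = load_scenario_files(cfg.bpmn_path, cfg.config_path, cfg.cohort_path)
    if cfg.horizon_min is not None:
        spec.horizon_min = cfg.horizon_min
    return spec


def config_digest(spec: ScenarioSpec) -> str:
    """Stable content hash of a scenario, for reproducibility logging."""
    blob = (
        to_bpmn(spec.graph)
        + yaml.safe_dump(hospital_to_dict(spec.hospital), sort_keys=True)
        + yaml.safe_dump(task_meta_from_graph(spec.graph), sort_keys=True)
        + yaml.safe_dump(groups_to_list(spec.groups), sort_keys=True)
        + yaml.safe_dump(modifiers_to_list(spec.modifiers), sort_keys=True)
        + cohort_to_frame(spec.cohort).to_csv(index=False)
        + f"{spec.seed}/{spec.horizon_min}"
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
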