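"""Performance indicators and scenario sweep drivers.

The primary indicator is per-patient *delay*: before evaluating a
scenario, the undelayed treatment duration of each injury group is
measured by sending one patient of that group through the process alone,
with all scenario modifiers stripped — the "best pathway" baseline.  The
delay of a patient in a scenario run is then
``(completion − arrival) − baseline(group)``.  When TTD/TTR clocks are
configured, the counts of damaged and removed patients are the
patient-outcome indicators.

Three sweep drivers mirror the cyber-risk questions the simulator is
for: rising device outage duration, degraded device efficiency, and
mass-casualty emergency plans (boosting trauma-room efficiency, with and
without a second CT scanner).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .engine import ScenarioSpec, SimulationResult, simulate
from .errors import InvalidScenario, MissingBaseline
from .hospital import Modifier, ResourceInstance
from .patients import Patient


@dataclass
class BaselineTable:
    """Per-group undelayed treatment duration in minutes."""

    minutes: dict[str, float]

    def __getitem__(self, group_id: str) -> float:
        return self.minutes[group_id]


@dataclass
class IndicatorSummary:
    per_patient: list[dict]
    patients: int
    completed: int
    damaged: int
    removed: int
    mean_duration_min: Optional[float]
    mean_delay_min: Optional[float]
    max_delay_min: Optional[float]
    mean_baseline_min: Optional[float]

    @property
    def mean_pct_increase(self) -> Optional[float]:
        """100 × (mean actual − mean baseline) / mean baseline over completers."""
        if not self.mean_baseline_min:
            return None
        return 100.0 * (self.mean_duration_min - self.mean_baseline_min) / self.mean_baseline_min


@dataclass
class SweepResult:
    """Indicator summaries over a sorted grid of scenario variants."""

    kind: str
    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = ["grid_value", "mean_pct_increase", "mean_delay_min", "damaged", "removed"]
        extra = [c for c in (self.rows[0].keys() if self.rows else []) if c not in cols]
        return pd.DataFrame(self.rows, columns=cols + extra)


def _strip_for_baseline(spec: ScenarioSpec, group_id: str) -> ScenarioSpec:
    """One patient of the group, arriving at 0, no modifiers, pristine hospital."""
    probe = Patient(id=f"baseline_{group_id}", group_id=group_id, t_start_min=0.0)
    return ScenarioSpec(
        graph=spec.graph,
        hospital=spec.hospital.clone(),
        groups=spec.groups,
        cohort=[probe],
        modifiers=[],
        seed=spec.seed,
        horizon_min=spec.horizon_min,
    )


def compute_baseline(spec: ScenarioSpec) -> BaselineTable:
    """Undelayed per-group durations: each group alone under optimal conditions.

    All modifiers (including beneficial ones) are stripped; inventories are
    as configured.  Independent of cohort composition by construction.
    """
    table: dict[str, float] = {}
    for gid in sorted({p.group_id for p in spec.cohort} | {g.id for g in spec.groups}):
        res = simulate(_strip_for_baseline(spec, gid))
        out = res.outcomes[f"baseline_{gid}"]
        if out["completion_min"] is None:
            raise InvalidScenario(f"baseline patient of group {gid} never completed")
        table[gid] = out["duration_min"]
    return BaselineTable(minutes=table)


def compute_indicators(result: SimulationResult, baselines: BaselineTable) -> IndicatorSummary:
    """Per-patient delays vs the baseline table plus cohort-level summary.

    Removed (reanimation) patients have no delay and are excluded from the
    means but counted; damaged completers keep their full timing.
    """
    rows = []
    for pid in sorted(result.outcomes):
        o = result.outcomes[pid]
        if o["group_id"] not in baselines.minutes:
            raise MissingBaseline(o["group_id"])
        base = baselines[o["group_id"]]
        delay = o["duration_min"] - base if o["duration_min"] is not None else None
        rows.append({
            "patient": pid, "group": o["group_id"],
            "t_start_min": o["t_start_min"],
            "duration_min": o["duration_min"],
            "baseline_min": base, "delay_min": delay,
            "damaged": o["damaged"], "removed": o["removed_reanimation"],
        })
    completers = [r for r in rows if r["duration_min"] is not None]
    delays = [r["delay_min"] for r in completers]
    return IndicatorSummary(
        per_patient=rows,
        patients=len(rows),
        completed=len(completers),
        damaged=sum(1 for r in rows if r["damaged"]),
        removed=sum(1 for r in rows if r["removed"]),
        mean_duration_min=(sum(r["duration_min"] for r in completers) / len(completers)
                           if completers else None),
        mean_delay_min=sum(delays) / len(delays) if delays else None,
        max_delay_min=max(delays) if delays else None,
        mean_baseline_min=(sum(r["baseline_min"] for r in completers) / len(completers)
                           if completers else None),
    )


def _summary_row(grid_value: float, summary: IndicatorSummary) -> dict:
    return {
        "grid_value": grid_value,
        "mean_pct_increase": summary.mean_pct_increase,
        "mean_delay_min": summary.mean_delay_min,
        "damaged": summary.damaged,
        "removed": summary.removed,
        "mean_duration_min": summary.mean_duration_min,
        "completed": summary.completed,
    }


def run_outage_sweep(
    spec: ScenarioSpec,
    resource_type_id: str,
    grid: Sequence[float],
    baselines: Optional[BaselineTable] = None,
) -> SweepResult:
    """Simulate the scenario under an outage of a type over ``[0, d)`` per grid point.

    ``d = 0`` injects nothing, so the identity point reproduces the
    unmodified run exactly.  Every grid point reruns the full simulation
    from the pristine spec.
    """
    baselines = baselines or compute_baseline(spec)
    result = SweepResult(kind="outage")
    for d in sorted(set(float(g) for g in grid)):
        mods = list(spec.modifiers)
        if d > 0:
            mods.append(Modifier(0.0, "resource_outage_start", resource_type_id))
            mods.append(Modifier(d, "resource_outage_end", resource_type_id))
        variant = _with_modifiers(spec, mods)
        summary = compute_indicators(simulate(variant), baselines)
        result.rows.append(_summary_row(d, summary))
    return result


def _with_modifiers(spec: ScenarioSpec, modifiers: list[Modifier]) -> ScenarioSpec:
    return ScenarioSpec(
        graph=spec.graph, hospital=spec.hospital.clone(), groups=spec.groups,
        cohort=spec.cohort, modifiers=modifiers, seed=spec.seed,
        horizon_min=spec.horizon_min)


def run_efficiency_sweep(
    spec: ScenarioSpec,
    resource_type_id: str,
    grid: Sequence[float],
    baselines: Optional[BaselineTable] = None,
) -> SweepResult:
    """Simulate with the type's efficiency set to each grid percentage at t=0.

    ``e = 100`` injects nothing, so that point is log-identical to the
    unmodified run.
    """
    baselines = baselines or compute_baseline(spec)
    result = SweepResult(kind="efficiency")
    for e in sorted(set(float(g) for g in grid)):
        if e <= 0:
            raise InvalidScenario(f"efficiency grid value must be > 0, got {e}")
        mods = list(spec.modifiers)
        if e != 100.0:
            mods.append(Modifier(0.0, "set_efficiency", resource_type_id, e))
        summary = compute_indicators(simulate(_with_modifiers(spec, mods)), baselines)
        result.rows.append(_summary_row(e, summary))
    return result


def ct_utilization(result: SimulationResult, spec: ScenarioSpec, type_id: str) -> float:
    """Busy fraction of a type's instances over its active span.

    Busy minutes of tasks that used an instance of the type, divided by
    (instance count × span from first such task start to last end).
    """
    iids = {iid for iid, inst in spec.hospital.instances.items()
            if inst.type_id == type_id}
    intervals = []
    starts = {}
    for ev in result.events:
        if ev.kind == "task_start" and iids & set(ev.payload["instances"]):
            starts[(ev.payload["patient"], ev.payload["task"])] = ev.time_min
        elif ev.kind == "task_end":
            key = (ev.payload["patient"], ev.payload["task"])
            if key in starts:
                intervals.append((starts.pop(key), ev.time_min))
    if not intervals:
        return 0.0
    span = max(e for _, e in intervals) - min(s for s, _ in intervals)
    if span <= 0:
        return 0.0
    busy = sum(e - s for s, e in intervals)
    return busy / (span * len(iids))


def run_emergency_plan_comparison(
    spec: ScenarioSpec,
    boost_grid: Sequence[float],
    trauma_area_id: str,
    ct_type_id: str,
    ct_counts: Sequence[int] = (1, 2),
    baselines: Optional[BaselineTable] = None,
) -> pd.DataFrame:
    """Compare emergency plans on an overload cohort.

    For each boost percentage and CT count, every resource type homed in
    the trauma area except the CT gets efficiency ``100 + boost`` at t=0;
    optionally an extra CT instance is added.  Reports mean treatment
    duration, improvement vs the unboosted single-CT run, and CT
    utilization (the saturation diagnostic).
    """
    baselines = baselines or compute_baseline(spec)
    boost_types = sorted({
        inst.type_id for inst in spec.hospital.instances.values()
        if inst.home_area == trauma_area_id and inst.type_id != ct_type_id})
    rows = []
    ref_mean = None
    for n_ct in sorted(ct_counts):
        for boost in sorted(set(float(b) for b in boost_grid)):
            variant = _with_modifiers(spec, list(spec.modifiers))
            for k in range(n_ct - 1):
                proto = next(inst for inst in sorted(
                    variant.hospital.instances.values(), key=lambda i: i.id)
                    if inst.type_id == ct_type_id)
                extra = ResourceInstance(
                    id=f"{proto.id}_extra{k + 1}", type_id=ct_type_id,
                    home_area=proto.home_area)
                variant.hospital.instances[extra.id] = extra
            if boost != 0:
                for tid in boost_types:
                    variant.modifiers.append(
                        Modifier(0.0, "set_efficiency", tid, 100.0 + boost))
            res = simulate(variant)
            summary = compute_indicators(res, baselines)
            if ref_mean is None:  # first row: boost 0, smallest CT count
                ref_mean = summary.mean_duration_min
            rows.append({
                "boost_pct": boost,
                "ct_count": n_ct,
                "mean_duration_min": summary.mean_duration_min,
                "improvement_pct": (100.0 * (ref_mean - summary.mean_duration_min) / ref_mean
                                    if ref_mean else None),
                "ct_utilization": ct_utilization(res, variant, ct_type_id),
                "damaged": summary.damaged,
                "removed": summary.removed,
            })
    return pd.DataFrame(rows)
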