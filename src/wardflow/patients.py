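"""Patients, injury groups, AIS coding and TTD/TTR deadline bookkeeping.

Patients are the agents of the simulation.  Each belongs to an injury
group ``G`` — a set of patients with equivalent AIS ratings that share
path, durations, priority, and deadline ranges.  Two optional per-patient
clocks start at arrival: *TTD* (time till irreversible damage; reaching
it flags the process as failed for that patient, who nevertheless
continues) and *TTR* (time until cardio-pulmonary reanimation is needed;
reaching it removes the patient from the process).  Therapy tasks can
extend both clocks via per-task deltas applied at task completion;
diagnostic tasks (an x-ray, say) leave them untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import CountMismatch, UnclassifiedPatient

#: The nine AIS body regions, in canonical order.
AIS_REGIONS = (
    "head", "face", "neck", "thorax", "abdomen",
    "spine", "upper_extremity", "lower_extremity", "external",
)

#: AIS severity levels 1..6 (0 = uninjured).
AIS_SEVERITIES = ("minor", "moderate", "serious", "severe", "critical", "maximum")


@dataclass(frozen=True)
class AISProfile:
    """Severity 0–6 for each of the nine AIS body regions."""

    severities: tuple[int, ...]

    def __post_init__(self):
        if len(self.severities) != len(AIS_REGIONS):
            raise ValueError(f"AIS profile needs {len(AIS_REGIONS)} regions")
        for s in self.severities:
            if not (0 <= int(s) <= 6):
                raise ValueError(f"AIS severity out of range: {s}")

    @classmethod
    def from_mapping(cls, m: Mapping[str, int]) -> "AISProfile":
        unknown = set(m) - set(AIS_REGIONS)
        if unknown:
            raise ValueError(f"unknown AIS regions: {sorted(unknown)}")
        return cls(tuple(int(m.get(r, 0)) for r in AIS_REGIONS))

    def as_mapping(self) -> dict[str, int]:
        return dict(zip(AIS_REGIONS, self.severities))

    def __getitem__(self, region: str) -> int:
        return self.severities[AIS_REGIONS.index(region)]


@dataclass
class InjuryGroup:
    """A patient category with equivalent AIS rating.

    ``priority``: larger is treated first in resource queues.
    ``ttd_range_min`` / ``ttr_range_min``: optional uniform sampling
    ranges for patient generation.  ``branch_labels`` fixes this group's
    branch at conditional exclusive splits (split id -> branch label).
    """

    id: str
    ais_signature: AISProfile
    priority: int = 0
    ttd_range_min: Optional[tuple[float, float]] = None
    ttr_range_min: Optional[tuple[float, float]] = None
    branch_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for rng in (self.ttd_range_min, self.ttr_range_min):
            if rng is not None and rng[0] > rng[1]:
                raise ValueError(f"range lo > hi in group {self.id}: {rng}")


@dataclass
class Patient:
    """One simulated patient agent."""

    id: str
    group_id: str
    t_start_min: float
    ttd_initial_min: Optional[float] = None
    ttr_initial_min: Optional[float] = None
    ais: Optional[AISProfile] = None
    delta_log: list[tuple[str, float, float]] = field(default_factory=list)
    attached_resources: set[str] = field(default_factory=set)
    status: str = "waiting"  # waiting | in_task | in_transit | completed | removed_reanimation
    damaged: bool = False
    completion_min: Optional[float] = None


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def generate_patients(
    groups: Sequence[InjuryGroup],
    counts: Mapping[str, int],
    arrival_windows: Sequence[tuple[float, float, int]],
    seed: int,
) -> list[Patient]:
    """Generate a reproducible cohort.

    Patients are created round-robin over ``groups`` in list order (one
    per group per pass) until each group's count is exhausted; ids are
    ``P01, P02, ...`` in creation order.  Arrival windows fill in declared
    order, so two windows of six with six groups yield one patient per
    group per window.  For each patient, in creation order, three values
    are drawn from one ``numpy`` Generator stream: T_start uniform in the
    window, then TTD and TTR uniform in the group's ranges (skipped when a
    range is absent).  Identical inputs therefore give identical cohorts.
    """
    total = sum(int(counts.get(g.id, 0)) for g in groups)
    slots = sum(int(n) for _, _, n in arrival_windows)
    if total != slots:
        raise CountMismatch(f"cohort size {total} != window slots {slots}")

    rng = np.random.default_rng(seed)
    remaining = {g.id: int(counts.get(g.id, 0)) for g in groups}
    order: list[InjuryGroup] = []
    while any(remaining[g.id] > 0 for g in groups):
        for g in groups:
            if remaining[g.id] > 0:
                order.append(g)
                remaining[g.id] -= 1

    window_seq: list[tuple[float, float]] = []
    for lo, hi, n in arrival_windows:
        window_seq.extend([(float(lo), float(hi))] * int(n))

    width = max(2, len(str(total)))
    cohort: list[Patient] = []
    for i, g in enumerate(order):
        lo, hi = window_seq[i]
        t_start = float(rng.uniform(lo, hi))
        ttd = float(rng.uniform(*g.ttd_range_min)) if g.ttd_range_min else None
        ttr = float(rng.uniform(*g.ttr_range_min)) if g.ttr_range_min else None
        cohort.append(Patient(
            id=f"P{i + 1:0{width}d}",
            group_id=g.id,
            t_start_min=t_start,
            ttd_initial_min=ttd,
            ttr_initial_min=ttr,
            ais=g.ais_signature,
        ))
    return cohort


# ---------------------------------------------------------------------------
# Classification & deadlines
# ---------------------------------------------------------------------------

def ais_classify(
    profile: AISProfile,
    groups: Sequence[InjuryGroup],
    matcher: Optional[Callable[[AISProfile, AISProfile], bool]] = None,
) -> str:
    """Map an AIS profile to the group with the region-wise matching signature.

    The default matcher is exact equality over all nine regions; pass a
    ``matcher(profile, signature) -> bool`` to plug in a tolerance.
    """
    match = matcher or (lambda p, s: p.severities == s.severities)
    for g in groups:
        if match(profile, g.ais_signature):
            return g.id
    raise UnclassifiedPatient(f"no group signature matches profile {profile.severities}")


def effective_deadlines(
    p: Patient,
    completed_tasks: Iterable = (),
) -> tuple[Optional[float], Optional[float]]:
    """Absolute (TTD, TTR) deadlines given the tasks completed so far.

    ``ttd_abs = t_start + ttd_initial + Σ ttd_deltas``, and likewise for
    TTR; ``None`` where the clock is unconfigured.  ``completed_tasks``
    may contain task nodes (with ``ttd_delta_min``/``ttr_delta_min``) or
    ``(task_id, ttd_delta, ttr_delta)`` triples as stored in
    ``Patient.delta_log``.
    """
    d_ttd = 0.0
    d_ttr = 0.0
    for t in completed_tasks:
        if isinstance(t, tuple):
            d_ttd += t[1]
            d_ttr += t[2]
        else:
            d_ttd += t.ttd_delta_min
            d_ttr += t.ttr_delta_min
    ttd = p.t_start_min + p.ttd_initial_min + d_ttd if p.ttd_initial_min is not None else None
    ttr = p.t_start_min + p.ttr_initial_min + d_ttr if p.ttr_initial_min is not None else None
    return ttd, ttr
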