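"""Hospital structure: areas, transit times, resource inventories, modifiers.

Areas host resource instances and task execution.  A *quarantined* area
freezes everything inside it; a merely *deactivated* (blocked) area — the
local-blackout case — stops task execution but may still lend portable
resources out, down to its configured minimum stock.  Staff are resources
too, grouped by skill class; an optional *on-call* area models off-duty
physicians whose transit to anywhere is the hospital's average travel
time.

Scenario *modifiers* are timestamped state changes (area deactivation,
quarantine, transit-time changes, efficiency changes, resource outages).
They take effect at their minute with half-open effectivity
``[at_min, next change)``; activities already in flight complete under the
old parameters.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from .errors import NonPositiveEfficiency, UnknownArea, UnknownTarget

#: Instance states.  Every instance is in exactly one at any instant.
STATES = ("idle", "busy", "in_transit", "attached", "blocked")

MODIFIER_KINDS = (
    "deactivate_area",
    "reactivate_area",
    "quarantine_area",
    "lift_quarantine",
    "set_transit",
    "set_efficiency",
    "resource_outage_start",
    "resource_outage_end",
)


@dataclass
class Area:
    id: str
    name: str = ""
    active: bool = True
    quarantined: bool = False
    min_stock: dict[str, int] = field(default_factory=dict)
    on_call: bool = False


@dataclass
class TransitMatrix:
    """Directed inter-area transit durations in minutes; diagonal is zero."""

    minutes: dict[tuple[str, str], float] = field(default_factory=dict)

    @classmethod
    def from_symmetric(cls, entries: dict[tuple[str, str], float]) -> "TransitMatrix":
        m: dict[tuple[str, str], float] = {}
        for (a, b), t in entries.items():
            m[(a, b)] = float(t)
            m[(b, a)] = float(t)
        return cls(minutes=m)

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        try:
            return self.minutes[(a, b)]
        except KeyError:
            raise UnknownArea(f"no transit entry for {a!r} -> {b!r}") from None


@dataclass
class ResourceType:
    id: str
    category: str = "device"  # device | staff
    mobility: str = "portable"  # portable | stationary
    skill_class: Optional[str] = None
    attachable: bool = False

    def __post_init__(self):
        if self.mobility == "stationary" and self.attachable:
            raise ValueError(f"stationary type {self.id} cannot be attachable")
        if self.category == "staff" and self.mobility != "portable":
            raise ValueError(f"staff type {self.id} must be portable")


@dataclass
class ResourceInstance:
    id: str
    type_id: str
    home_area: str
    location: str = ""
    state: str = "idle"
    efficiency_pct: float = 100.0

    def __post_init__(self):
        if not self.location:
            self.location = self.home_area


@dataclass(frozen=True)
class Modifier:
    """A time-scheduled scenario change.

    ``target`` is an area id, a resource-type id, or an ``(a, b)`` area
    pair for ``set_transit``; ``value`` is minutes (set_transit) or a
    percentage (set_efficiency), unused otherwise.
    """

    at_min: float
    kind: str
    target: Union[str, tuple[str, str]]
    value: Optional[float] = None

    def __post_init__(self):
        if self.at_min < 0:
            raise ValueError("modifier at_min must be >= 0")
        if self.kind not in MODIFIER_KINDS:
            raise ValueError(f"unknown modifier kind {self.kind!r}")


@dataclass
class HospitalState:
    """Areas, transit matrix, inventories and live resource state."""

    areas: dict[str, Area]
    transit: TransitMatrix
    types: dict[str, ResourceType]
    instances: dict[str, ResourceInstance]
    avg_travel_min: float = 0.0
    outages: set[str] = field(default_factory=set)  # type ids currently down

    def clone(self) -> "HospitalState":
        return copy.deepcopy(self)

    def on_call_area(self) -> Optional[str]:
        hits = [a.id for a in self.areas.values() if a.on_call]
        return hits[0] if hits else None

    def instances_of(self, type_id: str) -> list[ResourceInstance]:
        return [self.instances[i] for i in sorted(self.instances)
                if self.instances[i].type_id == type_id]

    def validate(self) -> list[str]:
        """Structural checks mirroring the type invariants; violations as data."""
        v = []
        if sum(1 for a in self.areas.values() if a.on_call) > 1:
            v.append("multiple_on_call_areas")
        for iid in sorted(self.instances):
            inst = self.instances[iid]
            if inst.type_id not in self.types:
                v.append(f"unknown_type: {iid}/{inst.type_id}")
            if inst.home_area not in self.areas:
                v.append(f"unknown_home_area: {iid}/{inst.home_area}")
            if inst.state not in STATES:
                v.append(f"unknown_state: {iid}/{inst.state}")
        for (a, b), t in sorted(self.transit.minutes.items()):
            if a not in self.areas or b not in self.areas:
                v.append(f"transit_unknown_area: {a}->{b}")
            if t < 0:
                v.append(f"negative_transit: {a}->{b}")
        for aid in sorted(self.areas):
            for tid in sorted(self.areas[aid].min_stock):
                if tid not in self.types:
                    v.append(f"min_stock_unknown_type: {aid}/{tid}")
        return v


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def transit_time(
    state: HospitalState,
    a: str,
    b: str,
    at_min: float = 0.0,
    modifiers: Sequence[Modifier] = (),
) -> float:
    """Transit minutes from ``a`` to ``b`` effective at ``at_min``.

    The diagonal is always zero.  Entries touching the on-call area use the
    hospital's average travel time.  ``set_transit`` modifiers with
    ``at_min <= at`` override the base entry (latest wins, half-open
    effectivity).  When the engine has already applied modifiers to
    ``state`` in time order, call this without ``modifiers``.
    """
    if a not in state.areas or b not in state.areas:
        raise UnknownArea(f"unknown area in pair ({a!r}, {b!r})")
    if a == b:
        return 0.0
    on_call = state.on_call_area()
    value: Optional[float] = None
    if on_call is not None and (a == on_call or b == on_call):
        value = state.avg_travel_min
    else:
        value = state.transit.get(a, b)
    for m in modifiers:
        if m.kind == "set_transit" and m.at_min <= at_min and tuple(m.target) == (a, b):
            value = float(m.value)
    return value


def lendable_count(state: HospitalState, area_id: str, type_id: str) -> int:
    """How many instances of a type this area could lend out right now.

    Idle, non-attached, portable instances located in the area, minus the
    area's minimum stock for the type.  A quarantined area lends nothing;
    a merely deactivated area still lends (the local-blackout rule).
    Stationary types are never lendable.
    """
    if area_id not in state.areas:
        raise UnknownArea(area_id)
    area = state.areas[area_id]
    rtype = state.types[type_id]
    if area.quarantined or rtype.mobility == "stationary":
        return 0
    if type_id in state.outages:
        return 0
    idle = sum(
        1 for inst in state.instances.values()
        if inst.type_id == type_id and inst.location == area_id and inst.state == "idle"
    )
    return max(0, idle - area.min_stock.get(type_id, 0))


def effective_duration(nominal_min: float, efficiency_pct: float) -> float:
    """Scale a nominal duration by resource efficiency: ``nominal × 100 / e``.

    Halved efficiency doubles the duration; 200% efficiency halves it.
    """
    if efficiency_pct <= 0:
        raise NonPositiveEfficiency(f"efficiency must be > 0, got {efficiency_pct}")
    return nominal_min * 100.0 / efficiency_pct


# ---------------------------------------------------------------------------
# Modifier application
# ---------------------------------------------------------------------------

def apply_modifier(state: HospitalState, m: Modifier) -> HospitalState:
    """Mutate ``state`` to reflect modifier ``m``; returns ``state``.

    Pure state bookkeeping only: flag flips, matrix entries, efficiency,
    outage registry, and idle→blocked / blocked→idle transitions implied
    by quarantine and outages.  In-flight activity (busy / in-transit
    instances) is never touched here — the engine lets those finish under
    the old parameters and re-checks flags at release time.
    """
    kind = m.kind
    if kind in ("deactivate_area", "reactivate_area", "quarantine_area", "lift_quarantine"):
        if m.target not in state.areas:
            raise UnknownTarget(f"unknown area {m.target!r}")
        area = state.areas[m.target]
        if kind == "deactivate_area":
            area.active = False
        elif kind == "reactivate_area":
            area.active = True
        elif kind == "quarantine_area":
            area.quarantined = True
            for inst in state.instances.values():
                if inst.location == m.target and inst.state == "idle":
                    inst.state = "blocked"
        else:  # lift_quarantine
            area.quarantined = False
            for inst in state.instances.values():
                if (inst.location == m.target and inst.state == "blocked"
                        and inst.type_id not in state.outages):
                    inst.state = "idle"
    elif kind == "set_transit":
        a, b = tuple(m.target)
        if a not in state.areas or b not in state.areas:
            raise UnknownTarget(f"unknown area pair {m.target!r}")
        state.transit.minutes[(a, b)] = float(m.value)
    elif kind == "set_efficiency":
        if m.target not in state.types:
            raise UnknownTarget(f"unknown resource type {m.target!r}")
        if m.value is None or m.value <= 0:
            raise NonPositiveEfficiency(f"set_efficiency needs a positive value, got {m.value}")
        for inst in state.instances.values():
            if inst.type_id == m.target:
                inst.efficiency_pct = float(m.value)
    elif kind == "resource_outage_start":
        if m.target not in state.types:
            raise UnknownTarget(f"unknown resource type {m.target!r}")
        state.outages.add(m.target)
        for inst in state.instances.values():
            if inst.type_id == m.target and inst.state == "idle":
                inst.state = "blocked"
    elif kind == "resource_outage_end":
        if m.target not in state.types:
            raise UnknownTarget(f"unknown resource type {m.target!r}")
        state.outages.discard(m.target)
        for inst in state.instances.values():
            if (inst.type_id == m.target and inst.state == "blocked"
                    and not state.areas[inst.location].quarantined):
                inst.state = "idle"
    else:  # pragma: no cover - Modifier.__post_init__ guards this
        raise UnknownTarget(f"unknown modifier kind {kind!r}")
    return state
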