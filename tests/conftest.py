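"""Shared fixtures: tiny hand-built scenarios and the bundled ETR fixture."""

from __future__ import annotations

import pytest

from wardflow.engine import ScenarioSpec
from wardflow.fixtures import build_etr_fixture, build_minimal_fixture
from wardflow.hospital import (
    Area,
    HospitalState,
    ResourceInstance,
    ResourceType,
    TransitMatrix,
)
from wardflow.patients import AISProfile, InjuryGroup, Patient
from wardflow.process import parse_bpmn


def linear_bpmn(*task_ids: str) -> str:
    """A start -> t1 -> ... -> tn -> end document."""
    parts = ['<definitions xmlns="http://www.omg.org/spec/BPMN/20100524/MODEL">',
             '<process id="p"><startEvent id="start"/>']
    parts += [f'<task id="{t}"/>' for t in task_ids]
    parts.append('<endEvent id="end"/>')
    chain = ["start", *task_ids, "end"]
    for i, (a, b) in enumerate(zip(chain, chain[1:])):
        parts.append(f'<sequenceFlow id="f{i}" sourceRef="{a}" targetRef="{b}"/>')
    parts.append("</process></definitions>")
    return "".join(parts)


def one_area_hospital(**inventory: int) -> HospitalState:
    """One area 'er' stocked with ``inventory`` portable staff-like types."""
    types = {t: ResourceType(id=t, category="staff") for t in inventory}
    instances = {}
    for t, n in inventory.items():
        for i in range(n):
            iid = f"{t}_{i + 1}"
            instances[iid] = ResourceInstance(id=iid, type_id=t, home_area="er")
    return HospitalState(areas={"er": Area(id="er")}, transit=TransitMatrix(),
                         types=types, instances=instances)


def plain_group(gid: str = "g", priority: int = 1, **kw) -> InjuryGroup:
    return InjuryGroup(id=gid, ais_signature=AISProfile((0,) * 9),
                       priority=priority, **kw)


def one_task_spec(duration=10.0, n_instances=1, n_patients=1, **patient_kw):
    """start -> T(duration, 1 nurse) -> end with configurable stock/cohort."""
    graph = parse_bpmn(
        linear_bpmn("T"),
        {"T": {"area": "er", "duration_min": duration,
               "demands": [{"type": "nurse"}]}})
    hospital = one_area_hospital(nurse=n_instances)
    group = plain_group()
    cohort = [Patient(id=f"P{i + 1}", group_id="g", t_start_min=0.0, **patient_kw)
              for i in range(n_patients)]
    return ScenarioSpec(graph=graph, hospital=hospital, groups=[group],
                        cohort=cohort, horizon_min=10_000.0)


@pytest.fixture(scope="session")
def minimal_bundle():
    return build_minimal_fixture()


@pytest.fixture(scope="session")
def etr_bundle():
    return build_etr_fixture(0)


@pytest.fixture(scope="session")
def mci_spec(etr_bundle):
    return etr_bundle.scenarios["mci"]


@pytest.fixture(scope="session")
def std_spec(etr_bundle):
    return etr_bundle.scenarios["baseline"]
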