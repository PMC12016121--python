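"""Hospital state: transit queries, lending rules, efficiency, modifiers."""

import pytest

from wardflow.errors import NonPositiveEfficiency, UnknownArea, UnknownTarget
from wardflow.hospital import (
    Area,
    HospitalState,
    Modifier,
    ResourceInstance,
    ResourceType,
    TransitMatrix,
    apply_modifier,
    effective_duration,
    lendable_count,
    transit_time,
)


@pytest.fixture
def hospital():
    return HospitalState(
        areas={
            "etr": Area(id="etr", min_stock={"vent": 1}),
            "ct": Area(id="ct"),
            "oncall": Area(id="oncall", on_call=True),
        },
        transit=TransitMatrix.from_symmetric({("etr", "ct"): 5.0}),
        types={
            "vent": ResourceType(id="vent", category="device"),
            "ct_scanner": ResourceType(id="ct_scanner", mobility="stationary"),
        },
        instances={
            f"vent_{i}": ResourceInstance(id=f"vent_{i}", type_id="vent",
                                          home_area="etr")
            for i in (1, 2, 3)
        } | {"ct_1": ResourceInstance(id="ct_1", type_id="ct_scanner",
                                      home_area="ct")},
        avg_travel_min=20.0,
    )


class TestTransitTime:
    def test_diagonal_is_zero(self, hospital):
        assert transit_time(hospital, "etr", "etr") == 0.0

    def test_configured_entry(self, hospital):
        assert transit_time(hospital, "etr", "ct") == 5.0

    def test_modifier_halfopen_boundary(self, hospital):
        mods = [Modifier(60.0, "set_transit", ("etr", "ct"), 15.0)]
        assert transit_time(hospital, "etr", "ct", 59.0, mods) == 5.0
        assert transit_time(hospital, "etr", "ct", 60.0, mods) == 15.0

    def test_on_call_area_uses_average_travel(self, hospital):
        assert transit_time(hospital, "oncall", "etr") == 20.0
        assert transit_time(hospital, "ct", "oncall") == 20.0

    def test_unknown_area_raises(self, hospital):
        with pytest.raises(UnknownArea):
            transit_time(hospital, "etr", "nowhere")


class TestLendableCount:
    def test_idle_minus_min_stock(self, hospital):
        assert lendable_count(hospital, "etr", "vent") == 2

    def test_at_min_stock_nothing_lendable(self, hospital):
        hospital.instances["vent_2"].state = "busy"
        hospital.instances["vent_3"].state = "attached"
        assert lendable_count(hospital, "etr", "vent") == 0

    def test_quarantine_blocks_lending(self, hospital):
        apply_modifier(hospital, Modifier(0.0, "quarantine_area", "etr"))
        assert lendable_count(hospital, "etr", "vent") == 0

    def test_deactivated_area_still_lends(self, hospital):
        apply_modifier(hospital, Modifier(0.0, "deactivate_area", "etr"))
        assert lendable_count(hospital, "etr", "vent") == 2

    def test_stationary_never_lendable(self, hospital):
        assert lendable_count(hospital, "ct", "ct_scanner") == 0


class TestEffectiveDuration:
    @pytest.mark.parametrize("nominal,eff,expected", [
        (10, 100, 10.0), (10, 50, 20.0), (10, 200, 5.0), (10, 80, 12.5)])
    def test_scaling(self, nominal, eff, expected):
        assert effective_duration(nominal, eff) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(NonPositiveEfficiency):
            effective_duration(10, 0)


class TestApplyModifier:
    def test_set_efficiency(self, hospital):
        apply_modifier(hospital, Modifier(0.0, "set_efficiency", "ct_scanner", 80.0))
        assert hospital.instances["ct_1"].efficiency_pct == 80.0
        assert effective_duration(
            10, hospital.instances["ct_1"].efficiency_pct) == 12.5

    def test_quarantine_blocks_idle_instances_and_lift_restores(self, hospital):
        apply_modifier(hospital, Modifier(30.0, "quarantine_area", "etr"))
        assert all(hospital.instances[i].state == "blocked"
                   for i in ("vent_1", "vent_2", "vent_3"))
        apply_modifier(hospital, Modifier(60.0, "lift_quarantine", "etr"))
        assert all(hospital.instances[i].state == "idle"
                   for i in ("vent_1", "vent_2", "vent_3"))

    def test_outage_blocks_and_ends(self, hospital):
        apply_modifier(hospital, Modifier(0.0, "resource_outage_start", "vent"))
        assert hospital.instances["vent_1"].state == "blocked"
        assert lendable_count(hospital, "etr", "vent") == 0
        apply_modifier(hospital, Modifier(30.0, "resource_outage_end", "vent"))
        assert hospital.instances["vent_1"].state == "idle"

    def test_outage_survives_quarantine_lift(self, hospital):
        apply_modifier(hospital, Modifier(0.0, "resource_outage_start", "vent"))
        apply_modifier(hospital, Modifier(1.0, "quarantine_area", "etr"))
        apply_modifier(hospital, Modifier(2.0, "lift_quarantine", "etr"))
        assert hospital.instances["vent_1"].state == "blocked"

    def test_unknown_target_raises(self, hospital):
        with pytest.raises(UnknownTarget):
            apply_modifier(hospital, Modifier(0.0, "deactivate_area", "nowhere"))
        with pytest.raises(UnknownTarget):
            apply_modifier(hospital, Modifier(0.0, "set_efficiency", "nope", 50.0))

    def test_invalid_kind_rejected_at_construction(self):
        with pytest.raises(ValueError):
            Modifier(0.0, "explode_area", "etr")

    def test_validate_flags_multiple_on_call(self, hospital):
        hospital.areas["ct"].on_call = True
        assert "multiple_on_call_areas" in hospital.validate()
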