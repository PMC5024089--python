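"""Aspiration sequencing: reversal contract, volumes, capacity, TZL policy."""

import math

import pytest

from aspireprint import (
    Capillary,
    CapacityError,
    ReservoirError,
    TZLPolicy,
    check_capacity,
    check_plunger_speed,
    estimate_tzl,
    plan_build,
    plan_filament,
    segment_volume,
    stack_layers,
)
from aspireprint.fixtures import (
    gen_gradient_rectangle,
    gen_nested_squares,
    gen_three_segment_filament,
    gen_two_layer_T,
)
from aspireprint.planner import load_machine_config, save_machine_config
from aspireprint.slicer import FilamentPlan, Segment, decompose


class TestSegmentVolume:
    def test_closed_form(self):
        cap = Capillary(length=85.0, inner_diameter=0.5)
        assert segment_volume(24.0, cap) == pytest.approx(
            24.0 * math.pi * 0.25 / 4.0, rel=1e-12
        )
        assert segment_volume(0.0, cap) == 0.0

    def test_volume_scales_with_diameter_squared(self):
        v1 = segment_volume(10.0, Capillary(inner_diameter=0.5))
        v2 = segment_volume(10.0, Capillary(inner_diameter=1.0))
        assert v2 == pytest.approx(4 * v1)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            segment_volume(-1.0, Capillary())


class TestPlanFilament:
    def test_two_segment_filament_aspirates_in_reverse(self, machine):
        fil = FilamentPlan(index=0, start=(0.0, 0.25), direction=0, total_length=24.0)
        fil.segments = [Segment("A2", 12.0, 0.0), Segment("AC5", 12.0, 12.0)]
        plan = plan_filament(fil, machine.capillary, machine.tzl, machine.reservoirs)
        assert plan.aspirated_inks() == ["AC5", "A2"]
        assert plan.deposition_inks() == ["A2", "AC5"]

    def test_single_segment_no_waste_no_switch(self, machine):
        fil = gen_three_segment_filament(24.0, 24.0, ("AC3", "AC1"))
        plan = plan_filament(fil, machine.capillary, machine.tzl, machine.reservoirs)
        kinds = [s.kind for s in plan.steps]
        assert kinds.count("aspirate") == 1
        assert kinds.count("pre_extrude_waste") == 0
        assert plan.total_column_length == 24.0

    def test_center_filament_seven_aspirations_six_switches(self, machine):
        pat = gen_nested_squares([1.0] * 4, ["A1", "A2", "A3", "A4"])
        fils = decompose(pat, 0.5)
        fil = next(f for f in fils if len(f.segments) == 7)
        plan = plan_filament(fil, machine.capillary, machine.tzl, machine.reservoirs)
        kinds = [s.kind for s in plan.steps]
        assert kinds.count("aspirate") == 7
        assert kinds.count("pre_extrude_waste") == 6
        reservoir_moves = [s.ink_id for s in plan.steps if s.kind == "move_to_reservoir"]
        switches = sum(1 for a, b in zip(reservoir_moves, reservoir_moves[1:]) if a != b)
        assert switches == 6

    def test_reversal_invariant(self, machine):
        """Reversed aspiration ink order equals the deposition-order sequence."""
        pat = gen_gradient_rectangle(["A2", "AC1", "AC3", "AC5"], 6.0, 10.0)
        for fil in decompose(pat, 0.5):
            plan = plan_filament(fil, machine.capillary, machine.tzl, machine.reservoirs)
            assert list(reversed(plan.aspirated_inks())) == fil.ink_sequence()

    def test_aspirate_displacements_sum_to_filament_length(self, machine):
        pat = gen_nested_squares([1.0] * 4, ["A1", "A2", "A3", "A4"])
        fil = decompose(pat, 0.5)[3]
        plan = plan_filament(fil, machine.capillary, machine.tzl, machine.reservoirs)
        total = sum(
            s.plunger_displacement for s in plan.steps if s.kind == "aspirate"
        )
        assert total == pytest.approx(fil.total_length, abs=1e-9)

    def test_waste_excluded_from_deposited_column(self, machine):
        machine.tzl = TZLPolicy(pre_extrusion_um=200.0, plunger_speed=50.0)
        pat = gen_gradient_rectangle(["A2", "AC1", "AC3"], 4.0, 2.0)
        fil = decompose(pat, 0.5)[0]
        plan = plan_filament(fil, machine.capillary, machine.tzl, machine.reservoirs)
        assert plan.total_column_length == pytest.approx(12.0 - 2 * 0.2, abs=1e-12)
        deposit = [s for s in plan.steps if s.kind == "deposit"][0]
        assert deposit.plunger_displacement == pytest.approx(plan.total_column_length)

    def test_missing_reservoir_names_ink(self, machine):
        fil = gen_three_segment_filament(24.0, 4.0, ("AC3", "AC1"))
        del machine.reservoirs["AC1"]
        with pytest.raises(ReservoirError, match="AC1"):
            plan_filament(fil, machine.capillary, machine.tzl, machine.reservoirs)


class TestCapacity:
    def test_boundary_accepted(self):
        fil = gen_three_segment_filament(84.0, 4.0, ("AC3", "AC1"))
        assert check_capacity(fil.segments, Capillary(length=85.0)) == 84.0

    def test_overflow_reported(self):
        fil = gen_three_segment_filament(90.0, 10.0, ("AC3", "AC1"))
        with pytest.raises(CapacityError) as exc:
            check_capacity(fil.segments, Capillary(length=85.0))
        assert exc.value.overflow_mm == pytest.approx(5.0)

    def test_empty_column_ok(self):
        assert check_capacity([], Capillary()) == 0.0


class TestTZL:
    def test_baseline_policy_is_homogeneous(self):
        est = estimate_tzl(TZLPolicy(pre_extrusion_um=0.0, plunger_speed=50.0))
        assert est.homogeneous
        assert est.tzl_um == pytest.approx(50.0)

    def test_monotone_in_displacement_on_full_grid(self):
        for speed in (50.0, 75.0, 100.0):
            prev = -1.0
            for disp in range(0, 501, 50):
                est = estimate_tzl(TZLPolicy(pre_extrusion_um=disp, plunger_speed=speed))
                assert est.tzl_um >= prev
                prev = est.tzl_um

    def test_turbulent_speed_with_max_displacement_escalates(self):
        est = estimate_tzl(TZLPolicy(pre_extrusion_um=500.0, plunger_speed=100.0))
        assert est.flag == "millimeter-scale mixing"
        assert est.tzl_um >= 1000.0

    def test_turbulent_speed_alone_is_non_homogeneous(self):
        est = estimate_tzl(TZLPolicy(pre_extrusion_um=0.0, plunger_speed=100.0))
        assert not est.homogeneous

    def test_out_of_bounds_policy_rejected(self):
        with pytest.raises(ValueError):
            TZLPolicy(pre_extrusion_um=600.0)
        with pytest.raises(ValueError):
            TZLPolicy(plunger_speed=40.0)


class TestPlungerSpeed:
    def test_nominal_speed_ok(self):
        assert check_plunger_speed(50.0) == "ok"
        assert check_plunger_speed(99.0) == "ok"

    def test_turbulence_threshold_warns(self):
        assert check_plunger_speed(100.0) == "warn"

    @pytest.mark.parametrize("speed", [120.0, 49.0, 0.0, -5.0])
    def test_out_of_range_rejected(self, speed):
        with pytest.raises(ValueError):
            check_plunger_speed(speed)


class TestPlanBuild:
    def test_two_layer_build_plans_both_layers(self, machine):
        model = gen_two_layer_T("A2", "AC5", layer_height=0.5)
        plans = plan_build(model, machine)
        zs = sorted({p.filament.z for p in plans})
        assert zs == [0.0, 0.5]
        per_layer = len(plans) // 2
        assert per_layer == 20  # 10 mm layer / 0.5 mm filaments

    def test_serpentine_alternates_direction(self, machine):
        model = gen_two_layer_T("A2", "AC5")
        plans = plan_build(model, machine)
        starts = [p.filament.start[0] for p in plans[:4]]
        assert starts == [0.0, 10.0, 0.0, 10.0]

    def test_missing_reservoir_propagates(self, machine):
        model = gen_two_layer_T("A2", "AC5")
        del machine.reservoirs["AC5"]
        with pytest.raises(ReservoirError, match="AC5"):
            plan_build(model, machine)


def test_machine_config_yaml_roundtrip(machine, tmp_path):
    path = save_machine_config(machine, tmp_path / "machine.yaml")
    back = load_machine_config(path)
    assert back.capillary == machine.capillary
    assert back.reservoirs == machine.reservoirs
    assert back.deposit_feed == machine.deposit_feed
    assert back.tzl == machine.tzl
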