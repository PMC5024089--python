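"""Plan the four-ink nested-squares stiffness pattern.

Builds an 8 x 8 mm concentric-squares layer from inks A1-A4 (1-4 w/v%
agarose), decomposes it into 0.5 mm filaments and prints, for each filament,
its segment list and the aspiration volumes the planner derives. Filaments
crossing the center square carry seven segments of four inks — six ink
switches during aspiration.
"""

from aspireprint import (
    Capillary, MachineConfig, count_switches, plan_build, segment_volume,
    stack_layers,
)
from aspireprint.fixtures import gen_nested_squares

pattern = gen_nested_squares([1.0] * 4, ["A1", "A2", "A3", "A4"])
machine = MachineConfig(
    capillary=Capillary(length=85.0, inner_diameter=0.5),
    reservoirs={f"A{i}": (120.0 + 15 * i, -25.0, 4.0) for i in range(1, 5)},
)
plans = plan_build(stack_layers([pattern], 0.5), machine)

print(f"{len(plans)} filaments of {plans[0].filament.total_length:g} mm")
for plan in plans:
    fil = plan.filament
    segs = ", ".join(f"{s.ink_id}:{s.length:g}mm" for s in fil.segments)
    print(f"  filament {fil.index:2d} y={fil.start[1]:5.2f}  "
          f"{len(fil.segments)} segment(s), {count_switches(fil.segments)} switch(es)  [{segs}]")

center = max(plans, key=lambda p: len(p.filament.segments))
print("\nmost segmented filament (crosses the center square):")
for seg in center.filament.segments:
    v = segment_volume(seg.length, machine.capillary)
    print(f"  aspirate {seg.ink_id}: {seg.length:g} mm column = {v:.4f} mm^3")
print("aspiration order (LIFO):", " -> ".join(center.aspirated_inks()))
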