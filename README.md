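# aspireprint

Planning and virtual-printing toolkit for **aspiration-on-demand multimaterial
hydrogel deposition** — a fabrication scheme in which each extruded filament
is assembled *inside* a glass capillary by sequentially aspirating liquid
hydrogel inks, which then gel in place and are deposited as one multimaterial
line. The approach patterns chemical, mechanical, electrical and biological
properties (stiffness gradients, conductive tracks, cell-laden stripes)
within a single printed object.

The package is for people building or studying such printers: it turns a
labeled build model into executable aspiration sequences and G-code, and
verifies them on a virtual printer before any hardware runs.

## What it computes

- **Pattern model** (`aspireprint.pattern`): layers as label grids with
  physical pixel size (PNG/PGM label images + JSON sidecar, or a JSON
  rectangle dialect), stacked into multi-layer builds.
- **Slicer** (`aspireprint.slicer`): scanline decomposition into parallel
  filaments at the capillary diameter *d* (pitch *d* + gap), run-length
  extraction of single-ink segments along each centerline, switch counting,
  and pattern-fidelity metrics (per-ink agreement, jagged-edge length).
- **Aspiration planner** (`aspireprint.planner`): the LIFO capillary
  contract — the last-aspirated ink sits at the tip and deposits first, so
  inks are aspirated in *reverse* deposition order. Plunger displacement
  maps 1:1 to column length (same bore), so a segment of length *L* needs
  volume *V = L·πd²/4*. Capacity is bounded by the 85 mm capillary.
  Transition-zone-length (TZL) policy: pre-extrusion displacement
  (0–500 µm) and plunger speed (50–100 mm/min; 100 risks turbulent mixing).
- **Machine I/O** (`aspireprint.gcode`): a minimal Mach3-style G-code
  dialect (G21/G90, axes X Y Z A, deposition at F150) and a virtual printer
  that replays programs, tracks the ink column as a LIFO stack, enforces
  conservation (deposited + waste = aspirated, per ink), and reconstructs
  the deposited label map for fidelity checks.
- **Ink physics** (`aspireprint.inks`): Ostwald power-law viscosity
  η = K·γ̇ⁿ⁻¹ fitted by log–log least squares; gel point as the G′–G″
  crossover temperature; small-strain Hookean modulus σ = Eε on the 0–4 %
  window; series-circuit effective conductivity
  σ_eff = ΣLᵢ / Σ(Lᵢ/σᵢ); σ = L/(R·A) from resistance measurements; a
  reservoir printability window from gel points; lumped Newtonian cooling
  during ink switches.
- **Fixtures** (`aspireprint.fixtures`): parameterized generators for the
  canonical demonstration patterns (nested squares, conductivity gradient,
  three-segment filaments, two-layer "T", striped cell pattern) and
  synthetic characterization curves (shear sweeps, gelation curves,
  stress–strain), all deterministic under a seed.

## Worked example

```python
from aspireprint import MachineConfig, plan_build, simulate, fidelity, stack_layers
from aspireprint.fixtures import gen_nested_squares

pattern = gen_nested_squares([1.0]*4, ["A1", "A2", "A3", "A4"])   # 8x8 mm
machine = MachineConfig(reservoirs={f"A{i}": (120 + 15*i, -25, 4) for i in range(1, 5)})
plans = plan_build(stack_layers([pattern], 0.5), machine)
center = max(plans, key=lambda p: len(p.filament.segments))
print(len(plans), len(center.filament.segments), center.aspirated_inks())
```

prints `16 7 ['A1', 'A2', 'A3', 'A4', 'A3', 'A2', 'A1']`: the 8 mm layer
becomes 16 filaments of 0.5 mm; the filaments crossing the center square
carry **7 segments of 4 inks (6 ink switches)**, aspirated as the reverse
palindrome so they deposit in pattern order. Simulating the emitted G-code
and comparing the reconstructed map to the target gives per-ink agreement
1.0 and jagged-edge length 0 mm for this axis-aligned pattern.

The `examples/` directory has one narrative script per capability
(`plan_nested_squares.py`, `virtual_print_and_fidelity.py`,
`ink_characterization.py`, `conductivity_designs.py`); each prints the
numbers it computes and what they mean. A thin CLI mirrors the pipeline:
`aspireprint plan|simulate|fidelity|fit|conduct|fixtures`.

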