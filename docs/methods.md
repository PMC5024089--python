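# Methods

## The planning problem

Aspiration-on-demand printing assembles each extruded filament inside a
glass capillary before deposition: the plunger draws in liquid hydrogel
segments one reservoir at a time, the column gels on cooling, and a single
synchronized move extrudes the whole multimaterial line. Planning therefore
reduces to three coupled sub-problems: (1) decompose a labeled layer into
filaments and single-ink segments, (2) order and size the aspirations so the
column leaves the capillary in pattern order, and (3) keep the inks inside
their rheological operating window while doing so. This package solves all
three on an idealized but explicit machine model, and verifies plans on a
virtual printer rather than hardware.

## Geometry and slicing

Layers are label grids in mm with pixel cells half-open
`[x, x+px) × [y, y+px)`, x right, y up, origin lower-left. The default
raster is 0.1 mm/pixel — five pixels across a 0.5 mm filament — enough to
resolve lane-level fidelity at negligible cost. Filaments are parallel
scanlines at 0° or 90°, pitch = diameter + gap, first lane center half a
pitch from the origin so zero-gap lanes tile the extent exactly. Segment
boundaries land on pixel boundaries: the grid is ground truth and sub-pixel
edges are not resolvable, so no interpolation is attempted.

Runs shorter than a minimum aspiratable length (default 0.5 mm; there is a
practical lower bound on how short a region can be aspirated without its
interfaces merging, but no established value) are merged into the longer
neighbor; ties go to the preceding segment so the result is deterministic;
merging conserves total length exactly.

## The LIFO aspiration contract

The capillary is a LIFO column: the last ink aspirated sits at the tip and
exits first. The planner therefore aspirates in reverse deposition order —
this is stated nowhere as a machine rule but is forced by the physics, and
the test suite pins it with an asymmetric two-segment filament that only
deposits in pattern order when the reversal is applied. Because the plunger
bore equals the capillary bore, plunger displacement maps 1:1 to column
length: an aspirate step's displacement equals its segment's length, and a
segment's volume is `L·πd²/4`.

## Transition zones and waste bookkeeping

The mixed-ink transition zone at each interface is controlled by a
pre-extrusion of the previously aspirated ink into the next reservoir
(plunger displacement 0–500 µm) and by plunger speed (50–100 mm/min).
The TZL estimate is `baseline + displacement`, inflated ×4 at the
turbulent 100 mm/min speed and flagged non-homogeneous there
(millimeter-scale when the inflated estimate reaches 1 mm). Baseline
(50 µm) and inflation factor are placeholder calibration constants — the
underlying observations are qualitative ("several hundreds of
micrometers") — and are exposed as arguments for substitution by a measured
table.

Waste bookkeeping follows the physics: the pre-extruded sliver leaves the
column tip, so the deposited column is `Σ lengths − (k−1)·waste` and every
non-tip segment arrives short by the waste amount. With the default policy
(0 µm pre-extrusion, 50 mm/min — the integrity-preserving setting) deposited
maps match the plan exactly. Conservation — deposited + waste = aspirated,
per ink — holds in the simulator to 1e-9 mm³ regardless of policy. The
capacity bound is `Σ segment lengths ≤ 85 mm` (waste only shrinks the
column, so no extra margin is needed).

## G-code dialect and the virtual printer

No machine-code listing exists for this printer class, so the dialect is
declared, not inferred: G21/G90 preamble, axes X Y Z with A for the plunger
(absolute, mm), feeds in mm/min, four decimal places, `;` comments, `M2`
end. Deposition is one line — simultaneous XY traverse at 150 mm/min with a
proportional positive A move.

The simulator replays programs with no knowledge of the planner: a negative
A move must occur at a reservoir position (else error) and pushes that
reservoir's ink onto the column; a positive A move pops from the tip — into
the reservoir as logged contamination when stationary, or painted along the
travel path when the head moves. Underflow (extruding more than the column
holds) and unsupported words raise with line numbers. Painting assumes
axis-aligned deposition (all patterns here are axis-aligned; oblique
boundaries are represented by their rasterization, and the fidelity metric's
jagged-edge length quantifies the stair-stepping). TZL mixing is *not*
rasterized — interfaces are painted sharp and the per-interface TZL estimate
is reported in the trace as an uncertainty, since the transition zone is
characterized as a length, not a composition profile.

## Ink physics

- **Power law.** η = K·γ̇ⁿ⁻¹ is fitted by ordinary least squares on
  log η vs log γ̇ (deterministic, weights a log-spaced sweep's decades
  evenly, exact on noise-free data). Nonlinear LS would weight the
  high-viscosity end and add an optimizer dependency for no benefit here.
- **Gel point.** The G′–G″ crossover is located by linear interpolation of
  `log G′ − log G″` against temperature between bracketing samples; with
  multiple crossings the highest temperature is returned, because on
  cooling from the liquid state that is the first gelation event.
- **Modulus.** σ = Eε fitted through the origin on the 0–4 % strain window
  (prestrain is removed during measurement, so a free intercept would fit
  noise; one is available behind `intercept=True`).
- **Conductivity.** Segments in series share cross-section, so the
  effective specific conductivity is the length-weighted harmonic mean
  `ΣL / Σ(L/σ)`. Measured multimaterial filaments deviate from this rule —
  plausibly interfacial resistance — which is deliberately *not* modeled;
  an optional per-interface equivalent-length term (default 0) is the hook
  for anyone who wants to calibrate it.
- **Thermal.** Reservoir windows come from gel points plus a margin against
  a ceiling (50 °C suits plain agarose inks; 38 °C for the thermally
  reversible/cell-laden pair). Cooling during an ink switch uses lumped
  capacitance, `T = T_env + (T0−T_env)e^(−t/τ)` — a deliberate first-order
  stand-in for transient FEA, adequate because the relevant excursions are
  a few seconds against a time constant of tens of seconds; gelation risk
  is flagged purely by comparison with each ink's crossover temperature.

## Synthetic data: what it does and does not show

The fixture generators reproduce the *documented topology and parameters* of
the demonstration objects — segment counts (7 segments/6 switches through
the nested-squares center), conductivity-filament geometry (24 mm with
4/8/12 mm middles and 10/8/6 mm heads), band orders, flow indices (0.3,
0.26), the 35 °C crossover, the 500.4 kPa modulus, the 15 % strain
confinement — but not unpublished absolute dimensions (nested-square band
widths default to four 1 mm bands; the consistency index K, never reported,
defaults to 100 Pa·sⁿ). Noise-free curves satisfy their defining equations
exactly, so fit tests demonstrate *correct recovery*, not robustness to
instrument noise; noisy variants are lognormal/Gaussian and seeded.
Passing tests therefore validate the planning/fitting machinery, not
real-ink behavior: real rheology deviates from a pure power law at the sweep
ends, real interfaces mix, and real filaments have rounded ends and menisci
that the square-ended, sharp-interface raster ignores.

## Numerical choices

Lengths are floats in mm throughout; conservation and length-sum checks use
1e-9 tolerances (G-code round-trips through 4-decimal formatting, so
residuals are ≤ 1e-5 mm per move and cancel in the bookkeeping). Pixel
membership tests use a 1e-9 nudge with half-open intervals, and fixture
geometry keeps boundaries ≥ half a pixel from cell centers, so raster
assignment is exact. Degenerate inputs: empty segment lists, zero-size
patterns, out-of-window strain data, non-crossing moduli and missing
reservoirs all raise typed errors early rather than propagating NaNs;
filaments exceeding capacity raise rather than being split, since splitting
behavior on the real machine is undocumented.

## Limitations

Arbitrary slicing angles, STL/mesh input, travel-time optimization,
interface fluid dynamics, CNT percolation, and cell-viability modeling are
out of scope. The virtual printer validates geometry and volume accounting,
not print forces or gelation kinetics.
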